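"""Diagnostic plots: sheaf, partition-function curves, spectra.

The pruned-sheaf color convention: kept lines black, modulus-filter
removals red, slope-filter removals green.
"""

from __future__ import annotations

import numpy as np

from .multifractal import PartitionFunctions, Spectra
from .rescue import KEPT, REMOVED_MF, REMOVED_SF, PrunedSkeleton
from .skeleton import Skeleton, compute_sheaf

__all__ = ["plot_sheaf", "plot_partition_curves", "plot_spectra"]

_LABEL_COLORS = {KEPT: "black", REMOVED_MF: "red", REMOVED_SF: "green"}


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_sheaf(skel: Skeleton, pruned: PrunedSkeleton | None = None, *, ax=None,
               max_lines: int | None = 2000, alpha: float = 0.25):
    """Sheaf (log2 M vs log2 a per line); colored by removal label if a
    pruned skeleton is given."""
    ax = _get_ax(ax)
    sheaf = compute_sheaf(skel)
    idx = np.arange(sheaf.n_lines)
    if max_lines is not None and len(idx) > max_lines:
        idx = np.linspace(0, len(idx) - 1, max_lines).astype(int)
    for order, color in ((REMOVED_MF, "red"), (REMOVED_SF, "green"), (KEPT, "black")):
        if pruned is None and order != KEPT:
            continue
        for i in idx:
            if pruned is not None and pruned.labels[i] != order:
                continue
            y = sheaf.log2_moduli[i]
            ok = np.isfinite(y)
            ax.plot(sheaf.log2_scales[ok], y[ok],
                    color=color if pruned is not None else "black",
                    lw=0.4, alpha=alpha)
    ax.set_xlabel(r"$\log_2 a$  [px]")
    ax.set_ylabel(r"$\log_2 M$")
    return ax


def plot_partition_curves(pf: PartitionFunctions, kind: str = "h", *, ax=None):
    """h(q, a) or D(q, a) sums against ln a, one curve per moment q."""
    import matplotlib.pyplot as plt

    ax = _get_ax(ax)
    data = {"h": pf.h_num, "D": pf.d_num, "Z": pf.log2_z}[kind]
    x = np.log(pf.scales) if kind in ("h", "D") else np.log2(pf.scales)
    cmap = plt.get_cmap("viridis")
    for i, qv in enumerate(pf.q):
        color = cmap(i / max(1, len(pf.q) - 1))
        ax.plot(x, data[i], ".-", color=color, lw=0.8, ms=3, label=f"q={qv:g}")
    ax.set_xlabel(r"$\ln a$" if kind in ("h", "D") else r"$\log_2 a$")
    ax.set_ylabel({"h": r"$h(q,a)$", "D": r"$D(q,a)$", "Z": r"$\log_2 Z(q,a)$"}[kind])
    return ax


def plot_spectra(spectra: Spectra, *, axes=None):
    """h(q), D(q) and D(h) panels."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    ax_h, ax_d, ax_dh = axes
    ax_h.plot(spectra.q, spectra.h, "ko-", ms=3)
    ax_h.set_xlabel("q")
    ax_h.set_ylabel("h(q)")
    ax_d.plot(spectra.q, spectra.d, "ko-", ms=3)
    ax_d.set_xlabel("q")
    ax_d.set_ylabel("D(q)")
    h, d = spectra.dh
    ax_dh.plot(h, d, "ko-", ms=3)
    ax_dh.set_xlabel("h")
    ax_dh.set_ylabel("D(h)")
    return axes
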