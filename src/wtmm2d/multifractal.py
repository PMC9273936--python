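"""Partition functions and multifractal spectra over a WTMM skeleton.

The partition function sums, over the maxima lines alive at scale
``a``, the q-th power of each line's running supremum modulus:

    Z(q, a) = sum_{l in L(a)} [ sup_{a' <= a} M_l(a') ]^q

and scales as ``Z(q, a) ~ a^tau(q)`` for ``a -> 0+``.  For a monofractal
surface ``tau(q) = qH - 2`` is linear; curvature signals multifractality.
Rather than Legendre-transforming ``tau`` (numerically fragile), the
singularity spectrum is computed canonically through Boltzmann weights

    W(q, l, a) = sup_l^q / Z(q, a)

via the expectation sums ``h(q, a) = sum W ln sup`` and
``D(q, a) = sum W ln W``, whose slopes against ``ln a`` give ``h(q)``
and ``D(q)``.  The direct Legendre transform is kept only as a
cross-check (:func:`legendre_check`).

Negative moments weight the weakest lines, which is why low-modulus
artifact lines (e.g. from saturated plateaus) destroy the ``q < 0``
statistics; the usable q range is diagnosed by the goodness of the
per-q power-law fits (R^2 >= 0.99 over the fit window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .cwt import FIT_WINDOW
from .skeleton import MaximaLine, Skeleton

__all__ = [
    "default_q_grid",
    "PartitionFunctions",
    "Spectra",
    "sup_modulus",
    "partition_function",
    "boltzmann_weights",
    "compute_partition_functions",
    "ensemble_average",
    "fit_spectra",
    "legendre_check",
]

LN2 = float(np.log(2.0))

#: Fits with R^2 at or above this value count as acceptable power laws
#: when delimiting the usable range of statistical order moments.
R2_USABLE = 0.99


def default_q_grid() -> np.ndarray:
    """Statistical order moments q = -3 .. 5 in steps of 0.5."""
    return np.arange(-3.0, 5.0 + 1e-9, 0.5)


def _validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 1 or len(q) < 2 or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be a strictly increasing 1D array")
    if not np.any(np.isclose(q, 0.0)):
        raise ValueError("q grid must contain 0")
    return q


@dataclass
class PartitionFunctions:
    """Z(q, a) with the canonical expectation sums, on a (q, scale) grid.

    ``log2_z`` holds ``log2 Z(q, a)``; ``h_num``/``d_num`` are the
    Boltzmann-weighted sums of Eqs. ``sum W ln sup`` and ``sum W ln W``
    (natural-log units).  Scales where the skeleton has no lines carry
    -inf / NaN and are dropped from fits.
    """

    q: np.ndarray
    scales: np.ndarray
    log2_z: np.ndarray  # (nq, ns)
    h_num: np.ndarray  # (nq, ns)
    d_num: np.ndarray  # (nq, ns)
    n_lines: np.ndarray  # (ns,)
    n_surfaces: int = 1
    meta: dict = field(default_factory=dict)

    def same_grids(self, other: "PartitionFunctions") -> bool:
        return (
            self.q.shape == other.q.shape
            and np.allclose(self.q, other.q)
            and self.scales.shape == other.scales.shape
            and np.allclose(self.scales, other.scales)
        )


@dataclass
class Spectra:
    """Fitted multifractal spectra with per-q diagnostics."""

    q: np.ndarray
    tau: np.ndarray
    h: np.ndarray
    d: np.ndarray
    r2_tau: np.ndarray
    r2_h: np.ndarray
    r2_d: np.ndarray
    fit_window: tuple[float, float]
    n_scales: int
    q_usable: tuple[float, float] | None

    @property
    def dh(self) -> tuple[np.ndarray, np.ndarray]:
        """(h, D(h)) pairs from the canonical spectra."""
        return self.h, self.d

    def hurst_estimate(self, q_range: tuple[float, float] = (-2.0, 2.0)) -> tuple[float, float]:
        """Slope and intercept of tau(q) over ``q_range`` — the Hurst
        exponent estimate (and -2 support check) for monofractals."""
        sel = (self.q >= q_range[0] - 1e-9) & (self.q <= q_range[1] + 1e-9)
        slope, intercept = np.polyfit(self.q[sel], self.tau[sel], 1)
        return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# Elementary operations (line-level, used by tests and small studies)

def sup_modulus(line: MaximaLine, a: float) -> float:
    """Running supremum of the line's modulus over scales <= ``a``."""
    if a > line.a_max * (1 + 1e-12):
        raise ValueError(f"scale {a} beyond the line's a_max={line.a_max}")
    sel = line.scales <= a * (1 + 1e-12)
    return float(line.moduli[sel].max())


def _log_sup_at(skel: Skeleton, j: int) -> np.ndarray:
    """ln sup-modulus at scale index j for every line in L(a_j)."""
    members = skel.j_max >= j
    if not members.any():
        raise ValueError(f"no maxima lines alive at scale index {j}")
    sub = skel.moduli[members, : j + 1]
    return np.log(np.max(sub, axis=1))


def partition_function(skel: Skeleton, q: float, a: float) -> float:
    """Z(q, a) for one moment and one grid scale (log-space internally)."""
    j = skel.grid.index_of(a)
    ls = _log_sup_at(skel, j)
    return float(np.exp(logsumexp(q * ls)))


def boltzmann_weights(skel: Skeleton, q: float, a: float) -> np.ndarray:
    """Normalized weights ``sup^q / Z(q, a)`` over L(a); sum to 1."""
    j = skel.grid.index_of(a)
    x = q * _log_sup_at(skel, j)
    return np.exp(x - logsumexp(x))


# ---------------------------------------------------------------------------
# Full grids

def compute_partition_functions(
    skel: Skeleton, q: np.ndarray | None = None
) -> PartitionFunctions:
    """Z, h-sum and D-sum on the full (q, scale) grid of one skeleton."""
    q = default_q_grid() if q is None else _validate_q(q)
    s = len(skel.grid)
    nq = len(q)
    log2_z = np.full((nq, s), -np.inf)
    h_num = np.full((nq, s), np.nan)
    d_num = np.full((nq, s), np.nan)
    counts = skel.counts()

    # prefix sup along each line, in log
    with np.errstate(divide="ignore"):
        logm = np.where(np.isnan(skel.moduli), -np.inf, np.log(skel.moduli))
    log_sup = np.maximum.accumulate(logm, axis=1)

    for j in range(s):
        members = skel.j_max >= j
        if not members.any():
            continue
        ls = log_sup[members, j]  # (m,)
        x = q[:, None] * ls[None, :]  # (nq, m)
        log_z = logsumexp(x, axis=1)
        log_w = x - log_z[:, None]
        w = np.exp(log_w)
        log2_z[:, j] = log_z / LN2
        h_num[:, j] = w @ ls
        d_num[:, j] = np.sum(w * log_w, axis=1)

    return PartitionFunctions(
        q=q,
        scales=skel.grid.scales.copy(),
        log2_z=log2_z,
        h_num=h_num,
        d_num=d_num,
        n_lines=counts,
        meta=dict(skel.meta),
    )


def ensemble_average(pfs: list[PartitionFunctions]) -> PartitionFunctions:
    """Arithmetic mean of Z, h-sum and D-sum per (q, a) across surfaces."""
    if not pfs:
        raise ValueError("need at least one PartitionFunctions")
    first = pfs[0]
    for pf in pfs[1:]:
        if not first.same_grids(pf):
            raise ValueError("all PartitionFunctions must share q and scale grids")
    n = len(pfs)
    stack_ln_z = np.stack([pf.log2_z * LN2 for pf in pfs])
    log2_z = (logsumexp(stack_ln_z, axis=0) - np.log(n)) / LN2
    h_num = np.mean([pf.h_num for pf in pfs], axis=0)
    d_num = np.mean([pf.d_num for pf in pfs], axis=0)
    counts = np.mean([pf.n_lines for pf in pfs], axis=0)
    return PartitionFunctions(
        q=first.q.copy(),
        scales=first.scales.copy(),
        log2_z=log2_z,
        h_num=h_num,
        d_num=d_num,
        n_lines=counts,
        n_surfaces=sum(pf.n_surfaces for pf in pfs),
    )


def _ls_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_spectra(
    pf: PartitionFunctions,
    fit_window: tuple[float, float] = FIT_WINDOW,
    *,
    r2_usable: float = R2_USABLE,
) -> Spectra:
    """Fit tau(q), h(q), D(q) over the scale window (pixels).

    tau(q) is the slope of ``log2 Z`` vs ``log2 a``; h(q) and D(q) are
    the slopes of the canonical sums vs ``ln a``.  The usable-q range is
    the maximal contiguous q interval containing q = 1 on which both
    the h- and D-fits reach R^2 >= ``r2_usable``.
    """
    lo, hi = fit_window
    sel = (pf.scales >= lo) & (pf.scales <= hi) & (pf.n_lines > 0)
    sel &= np.all(np.isfinite(pf.log2_z), axis=0)
    if np.count_nonzero(sel) < 4:
        raise ValueError(
            f"need >= 4 usable scales inside the fit window [{lo}, {hi}] px, "
            f"got {np.count_nonzero(sel)}"
        )
    log2_a = np.log2(pf.scales[sel])
    ln_a = np.log(pf.scales[sel])
    nq = len(pf.q)
    tau = np.empty(nq)
    h = np.empty(nq)
    d = np.empty(nq)
    r2_tau = np.empty(nq)
    r2_h = np.empty(nq)
    r2_d = np.empty(nq)
    for i in range(nq):
        tau[i], _, r2_tau[i] = _ls_fit(log2_a, pf.log2_z[i, sel])
        h[i], _, r2_h[i] = _ls_fit(ln_a, pf.h_num[i, sel])
        d[i], _, r2_d[i] = _ls_fit(ln_a, pf.d_num[i, sel])

    q_usable = _usable_range(pf.q, (r2_h >= r2_usable) & (r2_d >= r2_usable))
    return Spectra(
        q=pf.q.copy(),
        tau=tau,
        h=h,
        d=d,
        r2_tau=r2_tau,
        r2_h=r2_h,
        r2_d=r2_d,
        fit_window=(float(lo), float(hi)),
        n_scales=int(np.count_nonzero(sel)),
        q_usable=q_usable,
    )


def _usable_range(q: np.ndarray, ok: np.ndarray) -> tuple[float, float] | None:
    """Maximal contiguous ok-interval containing q = 1 (None if q = 1
    itself fails, or is absent from the grid)."""
    anchor = int(np.argmin(np.abs(q - 1.0)))
    if not np.isclose(q[anchor], 1.0) or not ok[anchor]:
        return None
    lo = anchor
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = anchor
    while hi < len(q) - 1 and ok[hi + 1]:
        hi += 1
    return float(q[lo]), float(q[hi])


def legendre_check(spectra: Spectra) -> float:
    """Cross-check the canonical D(q) against the direct Legendre
    transform ``D(h) = min_q (q h - tau(q))`` evaluated on the grid.

    Returns the maximum absolute deviation over interior q (endpoints
    excluded, where the grid minimum is one-sided).
    """
    q, tau, h, d = spectra.q, spectra.tau, spectra.h, spectra.d
    d_leg = np.array([np.min(q * h_i - tau) for h_i in h])
    interior = slice(1, -1) if len(q) > 2 else slice(None)
    return float(np.max(np.abs(d_leg[interior] - d[interior])))
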