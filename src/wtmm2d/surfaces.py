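"""Synthetic rough surfaces and controlled saturation.

Calibration inputs for the WTMM multifractal pipeline are isotropic
fractional Brownian motion (fBm) surfaces: Gaussian self-affine random
fields with Hurst exponent ``H`` in (0, 1), monofractal with Hölder
exponent ``h(x) == H`` everywhere.  Surfaces are synthesized by Fourier
filtering — shaping white Gaussian noise in the frequency domain by the
amplitude ``|k|^-(H+1)`` so that the power spectrum follows
``|k|^-2(H+1)`` — which makes them periodic by construction, matching the
FFT-based wavelet transform downstream.

Saturation is injected the way detector clipping acts on real images:
every pixel above the empirical ``(1 - level)``-quantile of the height
distribution is set to that critical value, producing perfectly flat
plateaus covering (at least) ``level`` of the image area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SaturationSpec",
    "RoughSurface",
    "synthesize_fbm",
    "fbm_ensemble",
    "apply_saturation",
    "write_surface",
    "read_surface",
]

#: Height range every synthetic surface is rescaled to before analysis.
#: A 10-bit convention ([0, 1023]), typical of the digitized mammograms
#: this analysis targets.  The rescue module's modulus-filter registry
#: is calibrated in these units: at the calibration size (1024 px) the
#: thresholds sit near the first percentile of the first-scale modulus
#: distribution of clean surfaces, so they separate flat-region
#: artifact lines from genuine ones.
DEFAULT_VALUE_RANGE = (0.0, 1023.0)


@dataclass(frozen=True)
class SaturationSpec:
    """Record of a saturation (clipping) operation.

    Attributes
    ----------
    level : float
        Requested fraction of pixels to saturate, in (0, 1).
    critical_value : float
        Height at which the surface was clipped (the empirical
        ``(1 - level)``-quantile of the original heights).
    achieved_fraction : float
        Fraction of pixels exactly equal to ``critical_value`` after
        clipping.  Always >= ``level``: ties at the quantile can only
        raise it.
    """

    level: float
    critical_value: float
    achieved_fraction: float


@dataclass
class RoughSurface:
    """A square grid of real heights plus provenance.

    Attributes
    ----------
    heights : ndarray
        ``N x N`` array of finite heights (arbitrary height units).
    hurst : float or None
        Hurst exponent used to synthesize the surface, if synthetic.
    seed : int or None
        RNG seed used to synthesize the surface, if synthetic.
    saturation : SaturationSpec or None
        Saturation applied to the surface, if any.
    periodic : bool
        Whether the surface is periodic (true for Fourier-synthesized
        fBm; imported images are not).
    """

    heights: np.ndarray
    hurst: float | None = None
    seed: int | None = None
    saturation: SaturationSpec | None = None
    periodic: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=np.float64)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError(f"heights must be a square 2D grid, got shape {h.shape}")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite everywhere")
        self.heights = h

    @property
    def size(self) -> int:
        """Side length N in pixels."""
        return self.heights.shape[0]


def _radial_frequency(n: int) -> np.ndarray:
    k = np.fft.fftfreq(n) * n  # integer frequencies
    return np.hypot(k[:, None], k[None, :])


def synthesize_fbm(
    hurst: float,
    size: int,
    seed: int,
    *,
    value_range: tuple[float, float] | None = DEFAULT_VALUE_RANGE,
) -> RoughSurface:
    """Synthesize a periodic fBm surface by Fourier filtering.

    White Gaussian noise is shaped in the frequency domain by the
    amplitude ``|k|^-(H+1)`` (DC term zeroed), giving an isotropic power
    spectrum ``|k|^-2(H+1)``.  The result has exactly zero mean and is
    then linearly rescaled to ``value_range`` (pass ``None`` to keep the
    raw zero-mean field).

    Parameters
    ----------
    hurst : float
        Hurst roughness exponent, in (0, 1).
    size : int
        Side length N in pixels; a power of two >= 64.
    seed : int
        Seed for the noise generator; the output is deterministic in it.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie strictly in (0, 1), got {hurst}")
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if size < 64 or (size & (size - 1)) != 0:
        raise ValueError(f"size must be a power of two >= 64, got {size}")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size, size))
    kr = _radial_frequency(size)
    with np.errstate(divide="ignore"):
        amp = np.where(kr > 0, kr ** -(hurst + 1.0), 0.0)
    heights = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    heights -= heights.mean()  # exact zero mean (DC already zeroed)

    if value_range is not None:
        lo, hi = value_range
        span = heights.max() - heights.min()
        heights = lo + (heights - heights.min()) * ((hi - lo) / span)

    return RoughSurface(heights, hurst=hurst, seed=seed, periodic=True)


def fbm_ensemble(
    hurst: float,
    size: int,
    n: int,
    ensemble_seed: int,
    *,
    value_range: tuple[float, float] | None = DEFAULT_VALUE_RANGE,
) -> list[RoughSurface]:
    """Generate ``n`` fBm replicates; replicate ``i`` uses seed
    ``ensemble_seed + i`` (recorded on each surface)."""
    return [
        synthesize_fbm(hurst, size, ensemble_seed + i, value_range=value_range)
        for i in range(n)
    ]


def apply_saturation(surface: RoughSurface, level: float) -> RoughSurface:
    """Clip the top ``level`` fraction of pixels to the critical value.

    The critical value is the empirical ``(1 - level)``-quantile of the
    heights, taken as an order statistic (the ``'lower'`` method), so
    that the clipped fraction is never below the requested level.  All
    heights strictly above it are set equal to it; the input surface is
    left unmodified.

    Raises
    ------
    ValueError
        If ``level`` is outside (0, 1) or the surface is constant
        (saturation of a flat surface is undefined).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"saturation level must lie strictly in (0, 1), got {level}")
    h = surface.heights
    if h.max() == h.min():
        raise ValueError("cannot saturate a constant surface")

    critical = float(np.quantile(h, 1.0 - level, method="lower"))
    clipped = np.minimum(h, critical)
    achieved = float(np.count_nonzero(clipped == critical)) / clipped.size
    spec = SaturationSpec(level=level, critical_value=critical, achieved_fraction=achieved)
    return replace(surface, heights=clipped, saturation=spec)


# ---------------------------------------------------------------------------
# I/O: float32 TIFF (primary) with a JSON metadata sidecar; 8/16-bit
# PNG/PGM accepted on import.

def write_surface(path: str | Path, surface: RoughSurface) -> Path:
    """Write a surface as 32-bit float TIFF plus a ``.json`` sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, surface.heights.astype(np.float32))
    meta = {
        "hurst": surface.hurst,
        "seed": surface.seed,
        "periodic": surface.periodic,
        "saturation": None
        if surface.saturation is None
        else {
            "level": surface.saturation.level,
            "critical_value": surface.saturation.critical_value,
            "achieved_fraction": surface.saturation.achieved_fraction,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_surface(path: str | Path) -> RoughSurface:
    """Read a surface from TIFF (float) or PNG/PGM (integer grayscale).

    If a ``.json`` sidecar written by :func:`write_surface` is present,
    provenance is restored; otherwise the image is treated as an
    imported, non-periodic surface.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        heights = np.asarray(tifffile.imread(path), dtype=np.float64)
    else:
        import imageio.v3 as iio

        heights = np.asarray(iio.imread(path), dtype=np.float64)
        if heights.ndim == 3:  # collapse RGB(A) to luminance
            heights = heights[..., :3].mean(axis=-1)

    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sat = meta.get("saturation")
        return RoughSurface(
            heights,
            hurst=meta.get("hurst"),
            seed=meta.get("seed"),
            saturation=None if sat is None else SaturationSpec(**sat),
            periodic=bool(meta.get("periodic", False)),
        )
    return RoughSurface(heights, periodic=False)
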