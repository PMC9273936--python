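# wtmm2d

2D Wavelet Transform Modulus Maxima (WTMM) multifractal analysis of
rough grayscale surfaces, with a skeleton-pruning **rescue** that
removes the artifact maxima lines created by image saturation
(clipping) so that valid multifractal statistics can still be computed
from images with up to ~20% saturated pixels.

The intended users are image-analysis researchers working with textured
medical or scientific imagery — the motivating case is sliding-window
mammogram analysis, where subregions are routinely rejected for
saturation — and anyone needing Hölder/Hurst roughness estimation of
2D fields with a validated synthetic-calibration path.

## Method in brief

A surface `f` is transformed with the Gaussian-derivative wavelets
`ψ₁ = ∂G/∂x`, `ψ₂ = ∂G/∂y` (`G = e^{-(x²+y²)/2}`):

    T_ψ[f](b, a) = (M, A),   M = √(T₁² + T₂²),  A = Arg(T₁ + iT₂).

Modulus maxima along the gradient direction form chains at each scale;
maxima along the chains (WTMMM) are linked across scales into maxima
lines (the skeleton). On a line pointing to a singularity of Hölder
exponent `h`, `M(a) ∼ a^h`. The partition function over lines alive at
scale `a`,

    Z(q, a) = Σ_l [sup_{a'≤a} M_l(a')]^q ∼ a^{τ(q)},

gives `τ(q) = qH − 2` for a monofractal surface of Hurst exponent `H`;
`h(q)` and `D(q)` are computed canonically from Boltzmann weights
`W = sup^q / Z` via the slopes of `Σ W ln sup` and `Σ W ln W` against
`ln a`, yielding the singularity spectrum `D(h)` without a Legendre
transform.

Saturated (clipped) regions are flat, hence not singular; they populate
the skeleton with extraneous lines that destroy the `q < 0` statistics.
The rescue removes them in two ordered stages: the **modulus filter**
(`M_first ≤ MF`, with `log₂ MF = 4` for H = 0.7 surfaces in 10-bit
units) and the **adjusted-slope filter**
(`m_adj = (log₂ M_first − log₂ M_last)/log₂ M_last ≥ SF = 0.5`).
See `docs/methods.md` for assumptions, parameter meanings and
limitations.

## Worked example

```python
import numpy as np
from wtmm2d import (synthesize_fbm, apply_saturation, build_skeleton,
                    prune, FilterParams, compute_partition_functions,
                    ensemble_average, fit_spectra)

# eight fBm surfaces, H = 0.7, clipped at the 20% level
params = FilterParams(mf=16.0, sf=0.5)
raw_pf, pruned_pf, removed = [], [], []
for seed in range(1000, 1008):
    surf = apply_saturation(synthesize_fbm(0.7, 1024, seed), 0.20)
    skel = build_skeleton(surf)
    pruned = prune(skel, params)
    removed.append(pruned.percentages)
    raw_pf.append(compute_partition_functions(skel))
    pruned_pf.append(compute_partition_functions(pruned.kept))

mf = np.mean([p["removed_MF"] for p in removed])
sf = np.mean([p["removed_SF"] for p in removed])
raw = fit_spectra(ensemble_average(raw_pf))
res = fit_spectra(ensemble_average(pruned_pf))
print(f"removed: {mf:.1f}% (modulus filter), {sf:.1f}% (slope filter)")
print(f"usable moments without rescue: {raw.q_usable}")
print(f"usable moments with rescue:    {res.q_usable}")
print(f"tau(q) slope after rescue:     {res.hurst_estimate()[0]:.3f}")
```

Output (about 90 s on one CPU):

```
removed: 25.8% (modulus filter), 1.3% (slope filter)
usable moments without rescue: (0.5, 5.0)
usable moments with rescue:    (-0.5, 5.0)
tau(q) slope after rescue:     0.622
```

Reading: the modulus filter removes ~26% of the lines (the plateaus
cover 20% of the image and their artifact lines slightly exceed the
area share), the slope filter a further ~1%. Without the rescue, no
moment below `q = 0.5` admits an acceptable power-law fit (R² ≥ 0.99);
with it, negative moments become usable again (extending further with
larger ensembles) and the fitted slope recovers the roughness of the
underlying surface (`H = 0.7`, with the method's known small
underestimate). On *unsaturated* surfaces the same pruning changes
`h(q)` and `D(q)` by less than 0.02 — it is safe to apply by default.

## Command line

```sh
wtmm2d synth --hurst 0.7 --size 1024 --n 8 --seed 12345 --out surfaces/
wtmm2d saturate --level 0.20 --in surfaces/ --out saturated/
wtmm2d skeleton --in saturated/fbm_H0.7_000.tif --out skel.h5
wtmm2d rescue --skeleton skel.h5 --mf 16 --sf 0.5 --out pruned.h5 --report report.csv
wtmm2d mf --skeleton pruned.h5 --out spectra.csv
wtmm2d run --out results/   # full calibration grid from a config
```

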