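# Methods

`wtmm2d` implements the two-dimensional Wavelet Transform Modulus Maxima
(WTMM) multifractal formalism for rough grayscale surfaces, together
with a skeleton-pruning "rescue" procedure that removes the artifact
maxima lines created by image saturation (clipping), restoring valid
multifractal statistics on images with up to ~20% saturated pixels.
This note records the model, the numerical choices, and what the
synthetic calibration does and does not establish.

## The model

A surface `f : R^2 -> R` is analyzed with the first-order wavelets
`psi_1 = dG/dx`, `psi_2 = dG/dy`, `G = exp(-(x^2+y^2)/2)`:

    T_i[f](b, a) = a^-2 ∫ psi_i((x-b)/a) f(x) d^2x,
    M = sqrt(T1^2 + T2^2),   A = Arg(T1 + i T2).

`(T1, T2)` is `-a` times the gradient of the Gaussian-smoothed surface
(times 2*pi), so `M` measures edge strength at scale `a` and `A` the
downhill direction. At each scale the WTMM — points where `M` is
locally maximal along `A` — form connected maxima chains; the local
maxima of `M` along the chains (WTMMM) are linked across scales into
maxima lines; the set of lines is the space-scale skeleton. Along a
line pointing to a singularity of Hölder exponent `h`, `M(a) ~ a^h` as
`a -> 0+` (valid for `h` below the wavelet order 1).

Global statistics come from the partition function over the lines
`L(a)` still present at scale `a`, with the supremum taken along each
line up to `a`:

    Z(q, a) = sum_l [sup_{a'<=a} M_l(a')]^q  ~  a^tau(q).

For a monofractal surface of Hurst exponent `H`, `tau(q) = qH - 2`.
Rather than Legendre-transforming `tau(q)` (numerically fragile, kept
only as a cross-check), `h(q)` and `D(q)` are estimated canonically
from Boltzmann weights `W = sup^q / Z`:

    h(q, a) = sum W ln sup,    D(q, a) = sum W ln W,

whose least-squares slopes against `ln a` over a fixed scale window
give `h(q)` and `D(q)`, hence the `D(h)` singularity spectrum.
Negative moments weight the weakest lines, which makes them exquisitely
sensitive to artifact lines — the effect the rescue corrects.

## Why saturation breaks the statistics, and what the rescue does

Clipping the top fraction `p` of pixels produces plateaus that are flat,
hence not singular anywhere; self-affinity is lost there. In the
skeleton this shows up as two artifact families that grow with `p`:
lines with extremely low modulus at the smallest scale (born inside the
plateaus, where the transform falls to its numerical noise floor — see
*Precision* below), and lines whose modulus decreases with scale
(features destroyed by the clipping). Both corrupt `h(q,a)` and
`D(q,a)` for `q < 0`: the weighted sums lock onto the weakest lines and
develop stair-step behavior, destroying the power-law fits and
collapsing the usable moment range to roughly `0 < q <= 5`.

The rescue prunes the skeleton in two ordered stages before the
partition functions are computed:

* **Modulus filter (MF)**: remove every line with first-scale modulus
  `M_first <= MF`.
* **Adjusted-slope filter (SF)**: among survivors, remove lines with
  `m_adj = (log2 M_first - log2 M_last) / log2 M_last >= SF`,
  where `M_last` is the modulus at the line's termination scale.

A line failing both tests is accounted under MF (the order makes the
two removal percentages additive). Calibrated defaults: `SF = 0.5`
for all roughness values and `MF` keyed by Hurst exponent — 16
(H=0.7), 48 (H=0.5), 96 (H=0.3), 192 (H=0.1). Rougher surfaces
(smaller H) retain relatively more small-scale energy, so their genuine
lines sit higher in modulus and tolerate a larger cut. On unsaturated
surfaces the same pruning is near-neutral: measured changes in `h(q)`
and `D(q)` for `q` in [-1, 3] are below 0.02 (ensembles of eight
1024-px surfaces).

Degenerate cases, decided here: a single-scale line has no slope and
faces the modulus filter only; when `log2 M_last <= 0` the ratio is
taken as +inf for a declining line (`M_first > M_last`, exactly the
artifact class) and -inf otherwise, extending the filter's intent
continuously. Both thresholds are inclusive.

## Synthetic calibration surfaces

Isotropic fractional Brownian motion (fBm) surfaces are synthesized by
Fourier filtering: white Gaussian noise shaped by the amplitude
`|k|^-(H+1)` (DC zeroed), inverse-transformed, giving a periodic,
zero-mean, monofractal field with `h(x) = H` everywhere. Heights are
then rescaled linearly to **[0, 1023]** — a 10-bit convention typical
of the digitized mammograms this method targets. The absolute scale
matters: both `MF` (a linear-units threshold) and `m_adj` (a ratio of
`log2` moduli) change meaning under rescaling. With the 10-bit range,
the calibrated `MF` registry sits near the first percentile of the
first-scale modulus distribution of clean surfaces at the calibration
size (1024 px), so it separates flat-region artifact lines from genuine
ones; `recalibrate_mf()` re-derives the threshold for data in other
unit conventions as the 1% quantile of clean first-scale moduli.

Saturation is injected by clipping at the empirical `(1-p)`-quantile of
the heights (the `'lower'` order statistic, so at least a fraction `p`
of pixels is clipped; the achieved fraction is recorded). Ensembles use
seed `ensemble_seed + i` for replicate `i`.

The calibration grid of the validation study: H in {0.1, 0.3, 0.5,
0.7}, saturation levels {1, 5, 10, 20}%, 1024x1024 surfaces. The
bundled tests and the acceptance script run ensembles of 6-16 surfaces
rather than 32 to keep single-CPU runtimes in minutes; ensemble-mean
removal percentages are stable at that size, while negative-moment
statistics (dominated by the few weakest lines) remain noticeably
noisier than at 32 replicates.

## Numerical choices

**Transform.** Kernels are built analytically in the frequency domain
(`psi_hat` of the Gaussian derivative), avoiding spatial sampling bias
at small scales; convolution is periodic (matching the periodic
synthetic surfaces). Imported non-periodic images are mirror-padded by
four times the largest scale and cropped. Scales follow a dyadic grid
`a_j = a0 * 2^(j/8)` with `a0 = 7` px up to `N/6`; spectral slopes are
fitted over the fixed window 17-56 px (at least 4 grid scales
required). Moments run from -3 to 5 in steps of 0.5.

**Precision.** The transform pipeline runs in single precision by
default, matching the numerical behavior of the field's C tooling; the
only visible consequence is deliberate and load-bearing: in exactly
flat image regions the exact transform decays monotonically to zero, so
a noise-free pipeline produces almost *no* maxima there, whereas a
single-precision FFT leaves a noise floor (~1e-7 of the field energy)
whose maxima populate saturated plateaus with the low-modulus artifact
lines that real float-based pipelines exhibit — the very lines the
modulus filter is calibrated to remove. `precision="double"` disables
this (and the saturation artifact model with it).

**Maxima detection.** The WTMM test compares `M(b)` with bilinear
interpolations at `b ± (cos A, sin A)` (strict on at least one side);
moduli below 1e-12 of the field maximum are discarded. WTMMM are
selected as chain points whose modulus is maximal among all WTMM within
a screening window of one scale `a` (Chebyshev); one representative per
plateau of equal-modulus maxima (first in scan order). The
scale-proportional window is essential: the modulus along a chain at
scale `a` is smooth at resolution `a`, so closer "maxima" are chain
breaks from the discretized directional test or noise ripples. Without
it the maxima count decays like `a^-1.3` instead of the `a^-2` required
by the support dimension, and `tau(0) = -2` / `D(0) = 2` are lost. A
greedy non-maximum suppression at radius `a` (strongest kept) then
removes duplicate detections across adjacent chains before linking.

**Linking.** Lines are seeded by every WTMMM at the smallest scale and
extended greedily in ascending distance order, one-to-one per scale
transition, within radius `1.5 * a_{j+1}` (periodic metric on periodic
surfaces). Unmatched lines terminate; unclaimed coarse-scale WTMMM do
not seed new lines, since only lines reaching the smallest scale carry
Hölder information in the `a -> 0+` limit. The radius factor 1.5 was
set on clean fBm so that the line count tracks the `a^-2` decay of the
available maxima (at 1.0 the one-to-one competition loses lines faster
than maxima disappear and `tau(0)` rises to about -2.2).

**Fits and diagnostics.** `tau(q)` is fitted on `log2 Z` vs `log2 a`
(base-invariant slope); `h(q)`, `D(q)` on the canonical sums vs `ln a`;
per-moment R^2 is recorded, and the usable moment range is the maximal
contiguous `q` interval containing `q = 1` with both `h`- and `D`-fit
R^2 >= 0.99 — a fixed, testable proxy for the visual "good power law"
judgment. Partition sums are evaluated in log space (log-sum-exp), so
arbitrarily large `|q|` cannot overflow.

## Measured behavior at the calibration conditions

Measured on ensembles of eight clean 1024-px H=0.7 surfaces: fitted
`tau(q)` slope ~0.62 (the well-known small underestimate of `H`, here
slightly accentuated by the fixed 17-56 px window), intercept ~-1.90,
`D(0)` ~1.89. At 20% saturation the raw usable range collapses to
about `0.5 <= q <= 5`; pruning with `log2 MF = 4`, `SF = 0.5` restores
the negative moments partially (to about `-0.5` at n=8, further with
larger ensembles), and removal percentages follow the calibrated
pattern: MF-removal grows monotonically with saturation (roughly the
saturated area fraction at high levels), SF-removal stays flat.

## Known limitations

* Negative-moment statistics are dominated by the few weakest surviving
  lines. In this implementation weak lines terminate earlier than in
  the original (unpublished) chaining heuristics, which (i) lowers the
  slope-filter removal share (about 1.5% at H=0.7 vs the reported ~5%),
  (ii) inflates `h(q)` for `q <= -1.5` on clean monofractal surfaces,
  and (iii) delays the R^2 >= 0.99 threshold for the rescued negative
  moments. Ensemble size mitigates but does not remove this.
* The saturation artifact model depends on the single-precision noise
  floor; analyzing in double precision makes flat regions nearly
  maxima-free, which changes removal percentages drastically (they
  become much smaller) while leaving clean-surface statistics intact.
* Calibrated `MF` values assume the 10-bit height convention; use
  `recalibrate_mf` for other ranges.
* Only `0 < H < 1` surfaces (wavelet order 1) and monofractal
  calibration are supported; multifractal synthesis is out of scope.
* The fBm generator emulates stationary-increment Gaussian self-affine
  fields with periodic boundaries. Real mammographic textures are
  non-Gaussian, nonstationary and non-periodic; passing the synthetic
  calibration shows the estimator and the rescue behave correctly on
  surfaces of known regularity, not that clinical images satisfy the
  model.
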