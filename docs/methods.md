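# Methods

## The comparison problem

A striated cut mark individualizes the blade that made it: edge damage on
the blade imprints a pattern of parallel ridges and valleys that is
(ideally) reproduced every time the blade cuts. Comparing two marks
therefore reduces to comparing two one-dimensional profiles across the
striations. `striamark` operates on regular height grids (S rows × P
columns, default 261 × 1004 at 3 µm/px — 262,044 points per scan, the
grid a striation scanner typically exports); rows run along the cut
direction, so each row is one cross-section signal.

## Signature construction

1. **Splitting.** A grid splits into its S rows; a flat point stream is
   chopped into consecutive blocks of P samples, discarding a partial
   remainder.
2. **Detrending.** Each signal has its centred moving average subtracted
   (default window 51 samples ≈ 153 µm: well above the striation spacing,
   below the wavelength of specimen form). At the signal ends the window
   shrinks symmetrically — equal reach on both sides — which makes the
   operator exactly annihilate affine signals, so adding any tilt or
   offset to a mark leaves the pipeline output unchanged to rounding.
3. **Alignment.** The normalized cross-correlation of two signals at lag L
   sums over the overlap region only, in the numerator and in both
   denominator terms. This choice (the summation bounds are otherwise
   ambiguous once a lag shifts indices out of range) keeps autocorrelation
   at exactly 1 and avoids zero-padding artifacts. Signals are aligned
   sequentially: signal 2 to signal 1, then each signal j ≥ 3 to the
   per-sample running mean of the already-aligned signals. The search is
   exhaustive over integer lags in ±max_lag (default ±50 samples); ties
   break toward the smaller |lag|, then toward the negative lag, for
   determinism. Shifted-out samples are invalidated, never wrapped —
   physical profiles are not periodic. No sub-sample interpolation is
   attempted: the data give no interpolation scheme to validate against,
   and integer lags keep the statistic exact.
4. **Averaging.** The signature is the per-sample mean over valid
   contributions. Samples covered by fewer than 90% of the signals are
   trimmed from both ends, bounding edge bias while retaining at least
   P − 2·max_lag samples.

Quality metrics: `X_max` is the plain mean of the S−1 step maxima (later
steps align against larger running means but are not weighted
differently), and `L_Xmax` is the mean of the *absolute* step lags —
signed lags would cancel, and the quantity is meant as a straightness
measure, so magnitudes are the natural aggregation.

## KM/KNM studies

The standard validation design is 10 knives × 2 marks per material: 10
known matches. Which cross-knife pairs serve as known non-matches is a
free choice; the default is a deterministic cyclic derangement (mark A of
knife i vs mark B of knife i+1), yielding exactly one KNM per knife and
reproducible pair sets; an `all-knm` scheme (all 2·2·C(n,2) cross-knife
pairs) is available. Signatures of unequal length are compared over their
common span, left-aligned. Group separation and cross-material contrasts
use the two-sided Mann–Whitney U test (exact distribution for combined
n ≤ 25, where the study's group sizes live; normal approximation with tie
correction beyond). Pairwise p-value tables are reported raw; Holm
adjustment is deliberately not applied by default to keep single-pair
inference unchanged, and callers can adjust externally.

## Photometry

Image contrast is the sample standard deviation (ddof = 1) of all pixel
brightness values in [0, 255]. The renderer exists to make the
reflectance law `I_R = I_I·|sin λ|·τ` operational on height maps: surface
normals from central differences, λ measured between the incoming ray and
the local tangent plane, facets facing away from the light clamped to
λ = 0. Brightness is `base + gain·I_R` with `base = 255·LRV/100` and the
gain calibrated so a 45° facet at τ = 1, I_I = 1 adds 64 counts;
quantization is round-half-away-from-zero with clamping to [0, 255], for
bit-identical output across platforms. The model intentionally omits cast
shadows, diffuse inter-reflection, translucency and diffraction — effects
real materials show but that the contrast metric does not require.
Instrument-specific processing (gamma, saturation) is out of scope.

## Indentation

Rigid-sphere elastic contact on an incompressible flat sample:
`F = (4/3)·E/(1−ν²)·√R·h^{3/2}` with E in MPa, R and h in mm, F in N
(dimensionally closed in these units). Curves are loading-only ramps,
re-zeroed after the preload, as in the emulated protocol (preload 0.1 N,
R = 1.5 mm, ν = 0.5, h_max = 0.9 mm, 0.5 mm/s, 50 Hz → 90 samples).

Two estimators are provided because a measured curve does not say whether
the modulus should be read pointwise or fitted: the default is an
origin-constrained least-squares regression of F on h^{3/2} (robust to
force noise), with a pointwise mean of per-sample moduli as the
alternative; the pointwise mean excludes h < 0.05·h_max, where the
h^{−3/2} factor amplifies noise without bound. Viscoelasticity, adhesion
and finite-thickness corrections are not modelled.

## Cleaning scores and statistics

Five binary criteria (coarse striations, fine striations, complete mark,
no shine, no dots) each score 1 when fulfilled; *no dots* alone may score
−1 when more dots appear than on the reference mark, so totals span
[−1, 5]. Total scores are treated as per-sample values, and the delta
score is the cleaned-sample mean minus the reference mean. The
summary-statistics t-test defaults to the Welch flavor (safe under
unequal variances) with the pooled flavor available, since reported
summaries rarely say which was used; the two agree closely at the group
sizes involved. The Kolmogorov–Smirnov normality wrapper uses the
Lilliefors correction (parameters estimated from the data), matching how
the test is applied in practice by statistics packages.

## The synthetic generator

The generator emulates what a striation scanner sees, not the cutting
mechanics:

* a **knife** is smoothed Gaussian noise (moving-average kernel of width
  correlation_length/dx, default 30 µm at 3 µm/px), rescaled to an exact
  amplitude sd (default 2 µm) — a stationary stand-in for edge damage;
* a **mark** repeats the knife profile across S rows with per-row integer
  lateral jitter (iid by default; a random-walk option models progressive
  drift, i.e. lower mark straightness), iid per-point height noise, a
  smooth form term (tilt + single-period bow) that detrending must remove,
  and optional **dots**: a spatial Poisson process of radially symmetric
  bumps whose diameters are normal (26.3 ± 5.1 µm) truncated to positive —
  the truncation correction is < 1% at these parameters. Dots are
  elevations because the emulated surfaces are casts (material filling
  cartilage lacunae); shifted rows are edge-extended, never wrapped, to
  avoid spurious periodic correlation;
* a **study** derives per-knife and per-mark sub-seeds from one root seed
  via seed sequences, so a configuration reproduces bit-identically.

Material presets (`high-fidelity`, `medium-fidelity`, `low-fidelity`,
`cartilage-like`) are invented engineering constants ordered so that
replication fidelity decreases monotonically in (jitter, noise); their
`E`, `tau` and `lrv` fields are documentation-level context, not fitted
material properties. What passing tests on synthetic studies show is that
the *pipeline* discriminates same-knife from different-knife marks under
the generator's statistical structure — shared profile plus independent
jitter/noise. Real cut marks add effects the generator does not model:
material tearing, blade rotation and tilt between cuts, non-stationary
striation amplitude, scanner artifacts. Synthetic KM scores near 1.0 are
therefore optimistic relative to physical studies, and KNM levels depend
on the knife correlation length; the generator supports method
validation, not material ranking.

## Numerical choices and problem sizes

* Correlations are accumulated in float64; the autocorrelation identity
  holds to 1e-12 and is asserted at that tolerance.
* Alignment failure (overlap < 3 samples at some step) raises rather than
  silently truncating; signature trimming below 10 samples likewise.
* Mesh resampling interpolates linearly within the containing triangle
  (exact for affine surfaces to 1e-9); folded meshes are detected by mixed
  orientation of the projected faces, and partially covered grids are
  trimmed by greedy border peeling to the largest fully covered rectangle
  (optimal for convex footprints).
* Test and validation runs use full-size 261 × 1004 studies where the
  design itself is under test, and reduced grids (e.g. 60 × 400) for
  parameter sweeps, where the monotonicity being checked does not depend
  on grid size.

## Known limitations

Integer-lag alignment bounds `X_C` resolution for sub-sample shifts; the
renderer is not radiometrically calibrated; the Hertz model assumes a
half-space (thin samples read stiff); the generator's jitter model is
per-row lateral shift only — it cannot produce locally curved striations
within a row.
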