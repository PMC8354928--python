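# striamark

Comparative analysis of striated tool marks in soft test materials, for
forensic researchers evaluating whether a material (an agarose gel, a
ballistic gelatine, a silicone…) reproduces knife cut marks faithfully
enough for examiner casework on costal cartilage.

When a blade cuts a soft material, microscopic irregularities on its edge
leave parallel striations. A 3D surface scan of the mark (or of its
silicone cast) is a regular height grid of S rows × P columns at a few µm
per pixel; each row is one cross-section profile through the striation
pattern. `striamark` implements the full comparison pipeline around the
overlap-normalized cross-correlation of two discrete profiles S₁, S₂ at an
integer lag L,

```
X(L) = Σᵢ S₁[i]·S₂[i+L] / sqrt( Σᵢ S₁[i]² · Σᵢ S₂[i+L]² ),
```

with all sums over the overlap region, so that autocorrelation at zero lag
is exactly 1:

* **profile pipeline** — split the grid into S signals, subtract a centred
  moving average (detrending removes tilt and form, keeps blade
  structure), sequentially align the signals at their best lags, average
  them into a single *signature*. The alignment yields two quality
  metrics: `X_max` (mean of the S−1 maximum step correlations; ≈ 1 for a
  consistent mark) and `L_Xmax` (mean |lag|; small for a straight mark).
* **signature comparison** — score mark pairs by the maximum
  cross-correlation `X_C`; organise known-match / known-non-match (KM/KNM)
  validation studies (n knives × 2 marks) and test score separation with a
  Mann–Whitney U test.
* **photometry** — the image contrast `IC` (sample sd of 0–255 pixel
  brightness), the reflectance law `I_R = I_I·|sin λ|·τ`, and a minimal
  oblique-light renderer for height maps.
* **indentation** — Hertzian spherical contact `F = (4/3)·E/(1−ν²)·√R·h^{3/2}`:
  forward simulation of ramp-loading curves and modulus estimation by
  origin-constrained regression or pointwise mean.
* **scoring & statistics** — the five-criterion cleaning score (total in
  [−1, 5]), delta scores, a summary-statistics t-test, and wrappers for
  the standard tests (Mann–Whitney U, Wilcoxon, Pearson, normality checks).
* **synthetic generator** — knives, marks, materials and whole KM/KNM
  studies with controllable jitter, noise, form and grain-like "dot"
  artifacts (diameter ≈ 26.3 ± 5.1 µm), so every stage is testable without
  scan data.

## Worked example

Simulate the standard validation design (10 knives, 2 marks each,
261 × 1004 grids at 3 µm/px) in a high-fidelity material and run the whole
pipeline:

```python
from striamark import ToolmarkStudy, StudyConfig, generate_study, material_presets

cfg = StudyConfig(material=material_presets()["high-fidelity"], seed=0)
result = ToolmarkStudy(generate_study(cfg), material="high-fidelity").fit()
print(result.summary())
```

```
Tool-mark study: high-fidelity
========================================
X_max:    0.996 +/- 0.000 (n=20)
L_Xmax:   0.588 +/- 0.032 (n=20)
X_C (KM):  1.000 +/- 0.000 (n=10)
X_C (KNM): 0.188 +/- 0.053 (n=10)
KM vs KNM Mann-Whitney p: 1.08e-05
```

Reading: the 20 marks are internally very consistent (`X_max` near 1,
sub-sample mean lags), same-knife signature pairs correlate near 1 while
different-knife pairs sit near 0.2, and the two score groups separate at
the smallest p-value an exact Mann–Whitney U test of 10 vs 10 can produce.

Estimating a Young's modulus from a simulated indentation ramp
(R = 1.5 mm sphere, ν = 0.5, 0.9 mm depth at 0.5 mm/s, 50 Hz):

```python
from striamark import HertzIndentationModel, simulate_indentation

curve = simulate_indentation(1.39, noise_sd=0.01, seed=0)
print(HertzIndentationModel(curve).fit().summary())
```

```
Hertz indentation fit
=====================
samples:        90 (h up to 0.900 mm)
indenter R:     1.5 mm, nu = 0.5
method:         regression
E_i:            1.3916 MPa (pointwise sd 0.0635)
rms residual:   0.009584 N
```

The same workflows are scriptable from the shell via the `striamark`
command (`simulate`, `signature`, `compare`, `batch-compare`, `contrast`,
`render`, `indent`, `scores`, `ttest-summary`, `report`).

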