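# Methods

## Phenology model

Each pixel-year's EVI trajectory is modelled as an asymmetric double
sigmoid, the difference of two logistic ramps sharing one background and
one amplitude:

    f(t) = V_b + V_a [σ(p (t − D_i)) − σ(q (t − D_d))],   σ(x) = 1/(1+e^−x)

This is the standard functional form for single-cycle crop phenology
retrieval: it has well-defined first/second derivatives, its parameters
map directly onto agronomic quantities (green-up and senescence mid-dates
and rates), and it degrades gracefully to the rising-only form
f(t) = V_b + V_a σ(p (t − D_i)) when the senescence limb has not yet been
observed (early-season mode). Multi-cycle (double-cropping) trajectories
are out of scope.

EVI is computed with the standard coefficients
2.5 (NIR − red)/(NIR + 6 red − 7.5 blue + 1); observations with a
non-positive denominator or EVI outside [−1, 1.5] are flagged invalid
rather than raising. A composite is usable only when all bands the
computation needs are flagged good.

### Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF)
with:

* bounds V_b ∈ [−0.2, 0.6], V_a ∈ [0, 1.2], p, q ∈ [0.01, 1] day⁻¹,
  D_i, D_d ∈ [1, 366];
* the falling mid-date parameterized as D_d = D_i + gap with gap ≥ 8
  days, so every fitted season has positive length;
* initial values from the data: V_b = 5th EVI percentile,
  V_a = 95th − 5th, D_i/D_d = first/last half-amplitude crossing,
  p = q = 0.1 day⁻¹; two restarts with the D_i guess shifted ±24 days
  guard against local minima;
* minimum 10 valid composites (6 in early mode); fewer, or optimizer
  failure, marks the pixel unfit and no-data propagates downstream.

On noise-free synthetic trajectories the fit recovers all six parameters
to ≈ 1e−11 days; with σ = 0.02 EVI noise the median |ΔD_i| over 100
pixels is ≈ 0.6 day (both measured by `scripts/acceptance.py`).

### Derived metrics

The second derivative of a logistic ramp has extrema where
σ = (1 ± 1/√3)/2, i.e. at the mid-date ∓ ln(2+√3)/slope. The 13 metrics
are V_b, V_a, p, q, D_i, D_d, the four transition dates
D_{1,2} = D_i ∓ ln(2+√3)/p, D_{3,4} = D_d ∓ ln(2+√3)/q, the season
lengths L_id = D_d − D_i and L_14 = D_4 − D_1, and D_peak. In full mode
D_peak is the argmax of the fitted curve over the observation window
(coarse grid + bounded scalar refinement); in early mode the fitted
rising sigmoid is monotone, so the argmax degenerates to the window end —
D_peak instead uses the DOY of the maximum valid *observed* EVI, ties
broken toward the earlier DOY.

**Known limitation.** The closed forms treat each logistic limb in
isolation. On the full double sigmoid the opposing limb's tail shifts the
inner inflections (D_2, D_3) by up to ~0.5 day at crop-like slopes
(p, q ≈ 0.07–0.2 day⁻¹, limbs 60–110 days apart); the outer ones (D_1,
D_4) are essentially unaffected. The closed forms are therefore treated
as the *definition* of the metrics (they are functions of the fitted
parameters), and the finite-difference second-derivative oracle used in
tests evaluates each limb separately, where agreement is ~0.01 day.

## Feature vectors

Seven spectral metrics — SWIR1 (band 6), SWIR2 (band 7), EVI,
NDTI = (b6−b7)/(b6+b7), VI64 = (b6−b4)/(b6+b4), DIF64 = b6−b4,
DIF67 = b6−b7 — are each evaluated at two phenological anchors: `avg`,
the mean over [D_i, D_d] (or [D_i, 224] in early mode, where D_d is
unknown), and `peak`, interpolated to D_peak. Reflectances are
averaged/interpolated first and indices computed from the aggregated
reflectances; the alternative (index first) differs only at second
order, and one convention is applied uniformly. Full-season vectors have
13 + 7×2 = 27 named variables, early-season 7 + 7×2 = 21; the early name
set is exactly the full set minus the six "late" metrics (q, D_d, D_3,
D_4, L_id, L_14).

Missing components (anchor outside the valid span, empty averaging
window) exclude a pixel from training; at prediction time they are
imputed with feature-wise training medians so maps stay total, and
all-missing pixels propagate no-data.

## Coverage targets and hard labels

Fine-grid labels (other = 0, corn = 1, soybean = 5, echoing CDL codes)
are aggregated in square blocks (default 16×16, standing in for the
30 m → 500 m footprint overlay, which would require projection-exact
geometry out of scope here). Percentages are exact block-count ratios;
`other%` is computed as 100 − (corn% + soybean%), which keeps the
three-band sum at exactly 100.0 in floating point (verified exhaustively
per factor). Hard labels require one class to exceed 75% strictly; the
same rule is applied to "other" for symmetry.

## Training-year selection and adjustment

Weekly cumulative progress series are interpolated linearly to the
50%-crossing DOY per (state, year, crop, stage); a series that never
reaches 50% yields a missing stage, and a first report already above 50%
is back-extrapolated from the first two points, clipped to at most 7 days
before the first report (sparse early reports otherwise produce absurd
dates). Corn and soybean stages are pooled into one vector per
state-year. Similarity between years is the RMSD over shared stages;
ties select the most recent year. The close-year control takes the year
immediately before the mapping year (the earliest mapping year takes the
following year instead).

Adjustments move mapping-year phenology into the training year's frame
(X_t = a + b X_v): A1 fits a and b by OLS of training-year on
mapping-year 50% dates over shared stages (≥ 2 required; b ≤ 0 is
rejected as degenerate); A2 fixes b = 1 with a the difference of means;
A0 is the identity. Date metrics transform affinely, length metrics
scale by b, rate metrics divide by b; spectral metrics and V_b/V_a are
never adjusted. One pooled adjustment covers both crops — per-crop
adjustment is deliberately avoided as over-fitting sparse stage data.

## Classification

`scikit-learn` random forests with k = 100 trees and m = 1 candidate
variable per split (accuracy is insensitive to k; m = 1 keeps training
cheap), seeded for determinism. Fuzzy mode trains one regressor per crop
on coverage percentages from all pixels of the training state-year; hard
mode trains a single 3-class classifier on pure pixels. Per-crop fuzzy
predictions are clipped to [0, 100]; when corn% + soybean% > 100 the
pair is rescaled proportionally (the reconciliation is otherwise
unconstrained) and other% takes the remainder.

## Validation

County crop area = Σ coverage/100 × pixel area over the county's pixels
(counties assigned at coarse-pixel centers). Agreement per crop is the
squared Pearson correlation between mapped and reference county-area
vectors (the regression form 1 − SS_res/SS_tot is recorded in report
metadata) plus the percentage difference of total area. The report also
carries a single pooled R² over the concatenated county×crop scatter:
per-crop Pearson R² is insensitive to class confusion that merely
rescales a crop's areas, while the pooled number degrades when the two
crops are biased in opposite directions, making it the right one-number
summary for comparing training-year strategies.

## Synthetic data

The simulator generates everything the pipeline consumes, with truth:

* **Landscape.** Rows/columns are cut into random intervals (8–40 cells)
  whose cross products form rectangular fields; fields receive classes by
  sampling with deficit-weighted probabilities, which matches the global
  proportions (default 35/35/30 corn/soybean/other) to within one field
  while a west–east weight gradient (±60% of the corn share, soybean
  opposite) reproduces the county-scale composition gradients of real
  agricultural regions.
* **Phenology.** Per-class parameter distributions (corn green-up
  mid-date 158 ± 6, senescence 245 ± 6; soybean 172 ± 6 / 258 ± 6;
  "other" a broad, low-amplitude cycle), a north–south green-up gradient
  of 14 days across the scene (the latitudinal planting progression
  within a state), a smooth year-specific anomaly field (sd 2 days,
  correlation length 4 coarse pixels — weather anomalies are regionally
  coherent but not uniform), and a per-year uniform shift δ (default
  years 2009/2010/2011 with δ = 0/+15/+5 days) emulating interannual
  variability. The 6-day within-class spread reflects a state's
  several-week planting window.
* **Reflectance.** Per class, red/blue/green/SWIR bands are affine in
  the noiseless greenness g(t) ∈ [0, 1] (class archetypes; corn and
  soybean differ mainly in SWIR–green contrast at peak), and NIR is then
  solved from the EVI formula so the EVI computed from the bands equals
  the double-sigmoid trajectory plus its N(0, σ = 0.02) observation
  noise exactly. Composites are flagged bad at rate 0.05, whole
  composites at a time. Coarse-pixel reflectance is the exact
  coverage-weighted mixture of the class trajectories.
* **Progress tables.** Simulator stage conventions: planted = D_1 − 12,
  emerged = D_1, silking/blooming = peak, dough/setting pods = peak + 12,
  dented/dropping leaves = D_3, mature = D_4, harvested = D_4 + 14.
  Weekly cumulative percentages are the normal CDF of the implied
  stage-date population (parameter spread ⊕ latitudinal gradient ⊕
  anomaly, plus a 1-day survey blur), so each stage's 50% date equals the
  population mean exactly and a δ-day year shift moves every 50% date by
  exactly δ.
* **Counties.** Square blocks of 2×2 coarse pixels (256 zones on the
  default 32×32 coarse grid) — a deliberately scaled-down analog of a
  multi-state county set chosen to keep the county-level R² estimate
  stable at desk scale.

The class separability was calibrated so the generator operates in the
regime the method is designed for: crops that are spectrally similar
enough that phenology carries much of the discrimination (making the
choice of training year matter), yet separable enough that a
well-matched training year maps both crops with county R² well above
0.9 and single-digit area bias. With fully distinct spectra the
training-year strategy becomes irrelevant; with phenology-only contrast
even a 5-day mismatch produces double-digit biases; neither emulates the
study conditions.

What the simulator does **not** contain: radiative-transfer or BRDF
effects, clouds/compositing artifacts, crop rotation structure between
years, double cropping, sub-pixel geolocation error, or survey noise in
the progress tables. Passing the end-to-end test therefore demonstrates
the internal consistency and cross-year logic of the pipeline under
controlled phenological variability, not performance on real imagery.

## Problem sizes and runtime choices

The end-to-end experiment uses a 512×512 fine grid aggregated 16× to
32×32 coarse pixels, three simulated years, and both training-year
strategies; one run fits ~3×1024 double sigmoids and takes ~2–3 minutes
on one CPU. Unit and property tests use smaller grids (64×64) and a few
hundred fits. Tolerances asserted in tests: 0.1 day for noise-free date
recovery (achieved ~1e−11), 2 days median for noisy D_i (achieved
~0.6), 0.05 day for the per-limb derivative oracle (achieved ~0.01),
exact equality for coverage sums, and R² ≥ 0.9 / |bias| ≤ 10% /
similar ≥ close pooled R² for the cross-year experiment.
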