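# Methods

This note documents the models, the defaults and the judgement calls behind
`petfuse`: what each stage computes, what the phantom cohorts emulate, and
what the tests do and do not establish about real data.

## Imaging conventions

Volumes are `(x, y, z)` arrays with strictly positive per-axis spacing in
millimetres; voxel `(i, j, k)` sits at `origin + (i, j, k) · spacing`.
Bounding boxes are half-open. All preprocessing transforms are pure
functions. NIfTI I/O and resampling delegate to SimpleITK; resampling
preserves the physical extent (`new_shape = round(shape · spacing /
target)`), uses linear interpolation for intensity images and nearest
neighbour for masks, and PET is brought onto the finer CT grid before any
voxelwise operation, since CT carries the higher anatomical resolution.

Intensity normalization uses the population standard deviation (divide by
n), matching the z-score formula as written, and can be restricted to a
region of interest. Contrast enhancement is a registry of monotone maps
(`none`, `log`, `histogram_equalization`, plus display-window clipping with
CT HU [−140, 260] and PET SUV [0, 12] as reference windows); the pipeline
default is `none` — which enhancement, if any, best serves feature
extraction is an open choice, and the identity is the conservative default.
PET input is assumed to already be in SUV; the only SUV-related rule
implemented is the data-cleaning convention that a missing body weight is
taken as 75 kg.

## Radiomic features

49 features per (volume, mask) pair, frozen in a versioned schema
(`petfuse.features.FEATURE_NAMES`): 14 first-order statistics, 11 shape
descriptors, and 24 texture features from GLCM (8), GLRLM (7), GLSZM (5)
and GLDM (4). Conventions, chosen once and applied everywhere:

* **Discretization** — default fixed bin count of 32 equal-width bins over
  the in-mask range; fixed bin width (anchored at the in-mask minimum) is
  available and is the better choice for PET when absolute SUV texture
  amplitude matters, because bin-count bins stretch with the range.
* **Directions** — the 13 unique 3D offsets; symmetric GLCM accumulation;
  per-direction features averaged over directions. The direction set is
  closed under 90° grid rotations, so direction-averaged features are
  rotation invariant on isotropic grids (a tested property).
* **Zones and dependence** — 26-connectivity; GLDM dependence counts
  neighbours within `alpha` gray levels (default 0), and emphasis terms use
  the dependence *size* (count + 1) so isolated voxels are well defined.
* **Conservation laws** (tested): GLRLM run lengths weighted by length,
  GLSZM zone sizes weighted by size, and the GLDM total all equal the
  in-mask voxel count; normalized GLCMs sum to 1. On small random grids
  every matrix is checked exactly against naive enumeration oracles.
* **Shape** — exposed-face surface area; sphericity `π^{1/3}(6V)^{2/3}/A`;
  maximum 3D diameter from surface-voxel centres (via convex hull when the
  surface is large); axis lengths `4√λ` from the second-moment ellipsoid.
* **Peritumoral context** — spacing-aware dilation by a Euclidean ball of
  physical radius r mm, computed exactly with a distance transform. The
  default mode is *inclusive* (tumor + margin), so the r = 0 arm is
  identical to the plain tumor analysis; a ring (margin-only) mode exists
  for sensitivity analyses. Radii are millimetres, not voxels.

The feature count is intentionally a frozen registry rather than a target
number; texture is computed on the mask's bounding box (in-mask voxels
only, so cropping cannot change the result).

## Weighted fusion

Both fusion levels realise the same convex combination with PET weight
`wp ∈ [0, 1]`, swept over {0.1, …, 0.9} by default:

* image level: `F = (1 − wp)·CT* + wp·PET*` on the common grid, where `*`
  is per-volume z-scoring — fusing raw HU with raw SUV would let CT
  dominate numerically at every weight;
* feature level: `g_k = (1 − wp)·z(ct_k) + wp·z(pet_k)` per paired feature,
  with per-feature z-scoring across patients.

The endpoints are identities (wp = 0 is the standardized CT arm, wp = 1 the
PET arm) and the image-level map is linear in wp — both tested bit-near.
The two levels are distinct experimental arms: features of the fused image
are not expected to equal fused features, and the suite asserts they
generally differ on heterogeneous phantoms. Modality combinations (CT_PET,
CT_WF, …) are column-wise concatenations with source-prefixed names.

## Survival model

Labels are `(time_days, event)` with recurrence = 1 and censoring = 0
(deaths censored). The model is two sklearn-style estimators:

* `ConcordanceFeatureSelector` — drop features with variance below a floor,
  rank the rest by |univariate Harrell C − 0.5|, keep greedily while
  pruning any candidate whose |Pearson r| with an already-kept feature
  exceeds the cap (defaults: 20 features, cap 0.95).
* `StackedSurvivalRegressor` — base learners regress `log(time)` on
  features over event-observed patients; a non-negative least-squares
  stacker is fit on out-of-fold base predictions and normalised, so the
  ensemble is a convex combination in log-time space. Risk is
  `−log(predicted time)`.

Censored patients are excluded from the regression loss — absolute-error
metrics (RMSLE, MAPE) against a censored time are not meaningful — but
enter the concordance index through every comparable pair. The default
learner registry is ridge, kNN (neighbour count capped at the training-set
size), random forest and gradient boosting; a compact ridge+kNN registry is
used for wide sweeps and permutation studies, where hundreds of refits are
needed and learner capacity is not the question. The registry is pluggable:
anything honouring fit/predict can be swapped in.

Arm evaluation uses stratified-by-event k-fold cross-validation (default
5), with selection and fitting redone inside each training fold. For
arm-versus-arm comparisons that hinge on C-index differences of a few
hundredths (the wp and radius sweeps), the C-index is averaged over three
independent fold splits (`repeated_cv_c_index`), shrinking split-to-split
jitter by √3. Every arm's table is population z-scored before modelling;
this makes the wp-endpoint identities exact at the pipeline level and is
idempotent on already-fused tables.

## Metrics and survival analysis

RMSLE `√(mean (log(ŷ+1) − log(y+1))²)`, MAPE `100/n · Σ|y−ŷ|/y` and Pearson
r (p from the two-sided t transform) are computed on event-observed
patients. The concordance index is Harrell's: pair (i, j) is comparable
when the smaller observed time is an event; risk ties score ½; with no
censoring and no ties it reduces to the plain indicator form. Kaplan–Meier
estimation is the product-limit estimator over distinct event times
(censored-only times reduce the at-risk count without a step), and group
comparison is the standard two-group log-rank χ² with 1 df. All four are
cross-checked in the tests against lifelines and against exhaustive
pair-enumeration / hand product-limit oracles. Risk stratification is a
median split with ties assigned to the low-risk group.

## Synthetic phantom cohorts

The generator emulates the structure of a multi-centre H&N PET/CT outcome
study at desk scale. Per patient, deterministically from `(spec, seed)`:

* **CT** (default 32³ at 2 mm): air background (−1000 HU), a soft-tissue
  body ellipsoid (40 HU), slightly denser lesions, Gaussian smoothing and
  15 HU noise.
* **PET** (same physical extent, default 4 mm grid): background ≈ 1 SUV,
  tumor uptake drawn per patient from U(3, 12) SUV, intratumoral
  heterogeneity as a smoothed Gaussian random field normalised to zero mean
  and unit sd *over tumor voxels* — so the uptake parameter is exactly the
  within-tumor mean and the heterogeneity parameter exactly the
  within-tumor sd — plus 0.15 SUV noise.
* **Physiological background** — 2–4 uptake blobs at U(2, 10) SUV
  (salivary-gland-like) and one dominant brain-like region at U(10, 15)
  SUV near the volume periphery. Their intensities are drawn independently
  of the outcome: they are pure distractors. Without them the phantom is
  degenerate for the peritumoral-context experiment — over a flat
  background, dilating the mask adds no noise and dilation-robust features
  (maximum, p90) keep the tumor signal at any radius, which no real image
  allows.
* **Lesions** — an ellipsoidal GTVp (radius U(6, 12) mm with ±20% axis
  jitter) and 0–3 spherical nodal lesions at 0.6× the primary's uptake.
* **Clinical covariates** — age, gender, weight (5% missing), tobacco,
  alcohol, performance status, HPV status, treatment, centre (nine
  centres); generated as noise by default, with an optional age effect.
* **Outcome** — exponential event time with log-linear hazard
  `η = β_u·uptake + β_h·heterogeneity + β_v·log(volume_cm³)` (defaults
  0.25, 0.5, 0.5), centred so times sit near the 1000-day baseline scale;
  independent uniform censoring whose bound is calibrated by Monte Carlo so
  the expected censored fraction matches `censor_rate` (default 0.3,
  verified to ±0.06 at n = 500).

What the phantoms do **not** emulate: anatomical realism, scanner physics
and reconstruction artefacts, multi-centre intensity shifts, correlated
clinical–imaging confounding, and non-proportional hazards. Passing tests
therefore establish the *mechanics* of the pipeline (no leakage, correct
statistics, recoverable planted signal), not clinical performance on real
cohorts.

## Study geometries used by the end-to-end checks

The heavy property checks run on deliberately small problems:

* **wp-sweep recovery**: 10 cohorts of n = 200 on 32³ grids with both
  PET-borne hazard channels active (β_uptake = 0.3, β_texture = 0.6,
  β_volume = 0) and nothing prognostic in CT. The fused-feature
  signal-to-noise factor is `wp/√(wp² + (1−wp)²)`, which rises with wp, so
  the sweep's best arm should sit at high PET weight; the check asks for
  argmax wp ≥ 0.7 in ≥ 8/10 cohorts and PET beating CT in ≥ 9/10. The
  texture channel matters: a strong uptake-only signal saturates the
  C-index and flattens the sweep's top, whereas texture features are weaker
  carriers that stay on the steep part of the attenuation curve.
* **radius sweep**: hazard confined to tumor uptake (β_uptake = 0.4, others
  0), on a wider field of view (48³ at 3 mm, with proportionally more
  background structures) so the largest dilation stays well inside the
  volume — on a small grid the r = 50 mm mask saturates to the whole image
  for every patient, which collapses the arms into one. The
  C-index-versus-radius trend should be negative.
* **null safety**: outcome permutations must hold every arm's mean CV
  C-index in [0.45, 0.55], and the log-rank test's false-positive rate at
  α = 0.05 is checked over 500 null replicates.

## Numerical choices and degenerate inputs

Constant volumes cannot be z-scored (degenerate-input error, never a
division by zero); a constant region discretizes to a single gray level,
for which GLCM correlation is undefined and reported as NaN (tables
median-impute non-finite entries before modelling). Empty masks, empty
bounding boxes, non-positive spacings and out-of-range weights raise typed
errors. Risk-score ties at the median go to the low-risk group; selector
ranking ties break by column order. The GLRLM run-length solver uses
pointer jumping (O(log max-run) whole-array passes) and was verified
exactly against a walk-every-run oracle.

## Known limitations

* The feature registry is compact (49 features); it covers every texture
  family but is far from an exhaustive IBSI registry (no filtered-image
  features, no 2D variants).
* RMSLE/MAPE on event-observed patients only is one defensible reading;
  with heavy censoring those metrics describe a biased subsample.
* The stacker is linear in log-time; strongly non-linear ensembles (full
  AutoML searches) are out of scope, though the registry accepts any
  regressor.
* Exponential outcomes make absolute-time prediction intrinsically noisy;
  MAPE values on phantoms are large even when ranking is good, and should
  be read comparatively, not absolutely.
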