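# Methods

`peradiomics` implements a complete single-slice CT radiomics analysis for
short-term mortality prognosis in acute pulmonary embolism (APE): feature
extraction from the skeletal-muscle (SM), intramuscular adipose tissue
(IMAT) and combined (SM+IMAT) compartments at vertebral level Th12,
perturbation-based robustness screening, redundancy clustering,
cross-validated occurrence-consensus signature selection, and held-out
evaluation against the sPESI clinical score. Because no patient imaging is
publicly deposited for this problem, the pipeline ships with — and is
validated on — a synthetic cohort generator that reproduces the statistical
structure the analysis assumes.

## Synthetic cohort model

Each patient is drawn from a latent-frailty model: a standard-normal
frailty `z` enters a logistic model for 30-day death whose intercept is
calibrated by Gauss–Hermite quadrature so the marginal mortality matches
the configured rate (default 14.6%; 7-day deaths are a nested Bernoulli
subset giving 8.4%). The same `z` drives the six sPESI components (age
> 80, cancer, chronic cardiopulmonary disease, heart rate ≥ 110, systolic
BP < 100, SaO2 < 90; five of them with logistic loadings plus a 5%
label-flip noise decoupled from outcome), so the clinical and radiomic
signals are correlated but not identical.

The image model renders, per patient, a 96×96 slice at 1.0 mm spacing with
an elliptical-band muscle compartment:

* **Geometry.** Outer ellipse with minor/major ratio equal to the
  patient's elongation (default 0.50 in decedents vs 0.65 in survivors,
  jitter SD 0.04), inner ellipse at 0.6 scale; random centre jitter and
  ±15° rotation. Compartments below 100 pixels are rejected.
* **Intramuscular fat.** A fraction of compartment pixels (default 20% in
  decedents vs 6% in survivors — the tissue-composition figures reported
  for the two outcome groups — with SD 0.025 jitter plus a small frailty
  leak) is covered by Poisson-seeded discs of 1–4 px radius, trimmed to the
  exact target count. Clustered speckles, not i.i.d. pixels, so grey-level
  size-zone structure exists. Fat HU ~ N(−48, 9).
* **Muscle attenuation.** Location-scale gamma distributions whose shape
  encodes myosteatosis: survivors centre at 33 HU (SD 20) with a *negative*
  tail (skew −1.15, ≈59% of muscle pixels above 30 HU); decedents centre at
  18 HU (SD 26) with a *positive* tail of residual normal muscle (skew
  +1.6, ≈24% above 30 HU). Draws are truncated below 150 HU (muscle does
  not straddle the SM window ceiling; an untruncated tail would punch
  spurious out-of-window holes into the combined ROI). Between-patient
  heterogeneity — location jitter SD 10 HU and ~12% scale jitter,
  emulating contrast-phase and scanner-calibration variability — makes the
  distribution *shape* (skewness), not its location, the reliable outcome
  marker, which is the behaviour the analysis is designed to detect.
* **Background** at −350 HU, outside every tissue window.

All randomness derives from one integer seed through per-patient
`SeedSequence` substreams: cohorts are byte-reproducible and extensible
without reshuffling existing patients. `CohortConfig.null_signal()` equates
all decedent image parameters with survivor values, decoupling images from
outcome while leaving the clinical signal intact — the negative control.

What the generator does **not** emulate: 3D anatomy, scanner-specific noise
and reconstruction kernels, segmentation error, partial-volume mixing at
tissue boundaries, or inter-centre protocol effects beyond a global
location/scale jitter. Passing tests therefore demonstrate that the
pipeline recovers the *kind* of signal the analysis posits under controlled
conditions; they are not evidence about any real cohort.

## Image preparation

Slices are resampled to 1.0×1.0 mm with order-3 spline interpolation
(mirror boundary; output pixel centres mapped into input index space).
Tissue masks are derived by HU thresholding inside the muscle compartment
with closed windows SM [−29, 150], IMAT [−190, −30], SM+IMAT [−190, 150]
(−30 HU belongs to IMAT, −29 to SM); masks are re-derived by thresholding
the resampled image, never interpolated. The LoG image averages
Laplacian-of-Gaussian responses at σ = 1…5 mm ("kernel width" read as the
Gaussian σ, converted to pixels through the spacing), computed after
resampling, with mirror padding; the small non-zero DC gain of the
truncated discrete kernels is removed exactly, so constant and affine
images map to zero response.

## Feature panel (234 per ROI)

25 morphology + 57 first-order (base image) + 95 texture + 57 first-order
(LoG image). The counts are fixed by a frozen manifest
(`peradiomics.features.manifest`); the field's naming convention is used
throughout (`stat_skew`, `morph_pca_elongation`, `szm_sze_2d_fbn_n24`,
`cm_sum_avg_d1_2d_s_mrg_fbn`, …), with `log_avg_` prefixes for LoG-derived
columns and IBSI codes recorded where established.

* **Discretization**: fixed bin number, 24 levels between the in-ROI min
  and max; the maximum maps to level 24; constant ROIs map to level 1 with
  a recorded warning. LoG first-order features use their own FBN
  discretization of the LoG intensities.
* **Morphology (25)**: area, perimeter, compactness/circularity variants,
  PCA axis descriptors (elongation = √(λ_minor/λ_major) of the pixel-centre
  cloud: 1 for a circle, 0 for a line; a single pixel is defined as 1 and
  flagged), convex-hull and bounding-box densities, approximate enclosing
  ellipse densities, component count and Euler number. Lengths in mm.
* **First-order (57)**: 18 statistics on raw HU (biased moment estimators
  for skewness/kurtosis, excess kurtosis), 2 local-intensity peaks over a
  100 mm² disc neighbourhood, 24 intensity-histogram features on the
  24-level discretization (including entropy, uniformity, mode and
  histogram-gradient features), 13 intensity–volume-histogram features on
  continuous HU with a 1000-point grid and linear interpolation for the
  intensity-at-volume-fraction values (`ivh_i50` etc.).
* **Texture (95 = 25 GLCM + 16 GLRLM + 16 GLSZM + 16 GLDZM + 5 NGTDM + 17
  NGLDM)**: distance 1; the four planar directions of the co-occurrence and
  run-length matrices are merged into one matrix *before* feature
  computation (the `s_mrg` convention); zones use 8-connectivity; distance
  zones use the city-block distance to the first out-of-ROI pixel (image
  borders count as outside, so edge pixels have distance 1); NGLDM uses
  coarseness parameter a = 0 and indexes dependence as count + 1.

Undefined values (empty ROI, single-pixel ROI, zero variance, single grey
level) are explicit NaN with a textual reason — never silent.

## Robustness screening

Five perturbed replicates per training slice: pixel-wise Gaussian noise
with the in-compartment SD, jointly with one ROI volume change from
{−10, −5, 0, +5, +10}%. Volume changes move the mask boundary along the
Euclidean distance transform (remove the shallowest / add the nearest
pixels) until the target pixel count is met exactly — the limit of
iterated one-pixel morphological steps without their quantisation error.
Features are re-extracted per replicate; agreement is quantified with the
one-way random-effects ICC(1,1) = (MSB − MSW)/(MSB + (k−1)·MSW) and its
exact F-based 95% CI. Features whose lower bound falls below 0.8 are
removed. A feature with zero total variance has ICC 1 by convention
(flagged); features with fewer than 5 complete patients are dropped with a
flag. The perturbation replicates are noise+volume *jointly* (five
replicates, one volume level each), and screening uses training patients
only.

## Redundancy clustering

Average-linkage hierarchical clustering on distance 1 − |Spearman ρ|
(average ranks for ties, pairwise-complete), dendrogram cut at mutual
|ρ| ≥ 0.8. Within each cluster the representative maximizes plug-in mutual
information with the endpoint (equal-frequency 10-bin discretization,
base 2; ties break lexicographically). Zero-variance features bypass
clustering (warned) and are excluded from the reduced table. Because MI
depends on the endpoint, representatives are endpoint-specific while the
cluster structure is shared.

## Signature search

Ten repeats of stratified 3-fold CV (30 runs) on the training split. Per
run, on the internal-training part only: per-feature Yeo–Johnson transform
(λ by maximum likelihood) followed by z-scoring; three selectors pick their
top-5 — MRMR (greedy difference criterion MI(f;y) − mean MI(f;selected)),
MIM (marginal MI), and univariate ridge-stabilized logistic regression
ranked by |Wald z|. The univariate ridge is deliberately non-trivial (1.0
on standardized features): an unpenalized Wald statistic collapses to zero
under complete separation (Hauck–Donner), which would rank a perfect
predictor last. Each learner — logistic regression, gradient-boosted
*linear* model (reducible by contract to a single linear score in the
transformed features), random forest — is tuned by random search over a
fixed grid scored by out-of-bag stratified-bootstrap AUC and scored on the
internal-validation fold.

Occurrence = percentage of the 30 runs in which a feature entered a
selector's top-5. The consensus rule — features above 50% occurrence in at
least two of the three selectors — is followed by correlation pruning: among
any candidate pair with training |ρ| > 0.5 only the higher mean occurrence
survives. An empty candidate set raises an explicit error rather than
returning silently. The final model refits the transformation and the
learner with the highest median CV AUC on the full training data.

## Evaluation

AUC is the Mann–Whitney estimator with half credit for ties; its 95% CI a
bias-corrected (BC, not BCa) stratified bootstrap with B = 2000; correlated
AUCs are compared with the paired DeLong test (placement values). The
classification cut-off maximizes Youden's J on training scores (ties toward
higher sensitivity; midpoint of the gap for separable scores; rule: score ≥
cut-off ⇒ predicted event) and is transferred unchanged to the test set.
Calibration uses the Hosmer–Lemeshow test over 10 equal-frequency
probability groups with g−2 df, merging degenerate groups. Per-feature
importance is the two-sided Wald p of univariate logistic fits on the
transformed features. The sPESI baseline uses the integer score as the
ranking statistic with the conventional cut-off 1.

## Pipeline and reproducibility

`run_all` orchestrates generate → prep → extract → screen → cluster → cv →
finalize → evaluate per ROI × endpoint, with a 70/30 split stratified
jointly on the nested 7-/30-day outcome (largest-remainder per-class
allocation). All thresholds live in `RunConfig` and are written into the
run manifest; artifacts are plain CSV/JSON (images NIfTI); per-stage
feature counts make the 234 → post-ICC → post-cluster funnel auditable. No
statistic computed on validation or test rows influences transforms,
selection, tuning or the cut-off; a test flips the held-out labels and
asserts the signature is unchanged.

## Problem sizes used by the test suite and acceptance script

Chosen to keep the default runs comfortably on one CPU:

* Acceptance script: one full SM+IMAT 30-day pipeline at n = 800 (the
  reference training/test sizes), full 10×3 CV with all three learners,
  8 tuning draws per CV fit and 32 for the final fit, bootstrap B = 2000.
* Parameter-recovery tests: 10 seeds per arm at n = 200 with 3 CV repeats
  and the boosted-linear learner; the null arm scores the fitted model on
  an independent 300-patient cohort, where the chance-AUC sampling SD
  (≈0.047) makes the [0.4, 0.6] chance band a meaningful assertion —
  at a 60-patient test split the SD alone is ≈0.10.
* Calibration suites: 500 bootstrap-coverage simulations (B = 500), 1000
  DeLong null simulations, 300 Hosmer–Lemeshow null simulations (fitted
  in-sample by logistic regression, matching the test's g−2 reference).

## Known limitations

* The 57-item first-order and 25-item morphology manifests are this
  package's frozen completion of the field's feature families; other
  toolkits ship slightly different memberships under the same counts.
* The synthetic image signal is stronger than any real cohort's (held-out
  AUC near 1 at default calibration): the recovery tests check direction
  and mechanics, not clinically realistic effect sizes.
* The boosted linear learner's reducibility contract is to a linear score
  in *transformed* features; the random forest has no such reduction.
* ICC is the one-way variant; perturbation replicates are not meaningful
  "raters", so two-way models are out of scope.
* Whether LoG filtering precedes or follows resampling is a convention;
  it is applied after resampling here, and LoG first-order features use
  their own discretization.
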