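# Methods

`glioscan` implements an integrated qualitative/quantitative MRI analysis
for glioblastoma: radiomics feature extraction from paired T1+Gd / T2
volumes, VASARI-coded qualitative features, prognostic Cox modeling with
prognostic-index (PI) stacking and multi-step external validation, and
molecular-marker classification with randomized model search. Because
clinical cohorts of this kind are not redistributable, the package ships a
synthetic multi-scanner cohort generator with recorded ground truth, so
every statistical claim the pipeline makes can be checked by parameter
recovery.

## Synthetic cohorts

Each synthetic patient is an ellipsoidal enhancing tumor (bright rim, dark
necrotic core) with an edema halo, drawn on a regular grid whose voxel
spacing comes from a per-patient `ScannerProfile`. Training and validation
cohorts draw from different profile mixtures, emulating two centers with
heterogeneous acquisitions. Artifacts:

* **Bias field** — a product of per-axis quadratic polynomials with random
  coefficients, normalized to unit mean and scaled so the peak deviation
  equals `bias_amplitude` (default 0.15–0.35 across demo profiles). Smooth
  and low-frequency, matching the multiplicative model N4 assumes.
* **Noise** — additive i.i.d. Gaussian (default 4–6 intensity units against
  tissue contrasts of 60–90 units). Real MR magnitude noise is Rician; at
  these SNRs the two are nearly indistinguishable, and Gaussian keeps the
  generator analytically transparent.

Survival times are exponential with hazard `h0 * exp(sum(beta_i x_i))` over
a declared subset of latent features (default: standardized log tumor
volume 0.5, edema extent 0.4, non-standard adjuvant regimen 1.6 — the last
mirroring the strong clinical hazard ratios reported for incomplete
chemoradiation), with `h0 = 0.05`/month and independent exponential
censoring at 0.012/month (≈15–20 % censoring, median survival near one
year at PI = 0). Molecular markers are Bernoulli draws from logistic models
over distinct latents, with a configurable missing fraction (default 5 %).
VASARI items are thresholded from the generating geometry (e.g.
multifocality is the second-lesion flag, edema category is the halo width
cut at 4 and 7 mm), so qualitative and quantitative blocks correlate the
way they do in real data. All randomness derives from one integer seed;
identical inputs give byte-identical cohorts.

The demo grids use 1.5–3 mm in-plane spacing over a 72×72×48 mm field of
view. These are deliberately coarser than clinical glioma protocols so a
full two-cohort study (simulation → N4 → filter banks → ~2300 features per
patient → all seven models) runs in about a minute; the preprocessing
default target (0.449 mm in-plane, 5.5 mm slices) is retained for
real-geometry input. Consequently the synthetic study exercises every code
path at realistic *statistical* scale but not at clinical *image* scale,
and it contains no anatomy, motion, or inter-sequence misregistration —
passing tests demonstrate correctness of the machinery, not clinical
performance.

## Preprocessing

Order: resample → N4 bias correction → global histogram equalization →
Z-score. Rationale and details:

* **Resampling** preserves the physical extent; in-plane interpolation is
  cubic-spline (4×4 support — reproduces affine intensity ramps exactly),
  through-plane is linear because thick slices make cubic overshoot risky.
  The default target is the modal spacing of the training cohort; the
  clinical values 0.449/5.5 mm are the config default for real data.
* **N4** runs via SimpleITK with a 2× shrink and (20, 20) iterations by
  default; the estimated log-field is resampled to full resolution and
  divided out. The field is estimated over the whole volume by default
  (the synthetic phantoms have no air background; for skull-stripped or
  real data a head mask can be passed). Exactly constant input returns
  unchanged (the field is 1 by definition; N4's histogram sharpening is
  undefined at zero variance). Non-convergence returns the input with a
  `converged: false` flag rather than failing silently.
* **Equalization** is the exact empirical-CDF map P(X ≤ x) over the whole
  volume — global, not adaptive, and rank-preserving. Together with the
  Z-score this makes the intensity pipeline invariant to any strictly
  monotone intensity warp of the input.
* **Z-score** parameters (mu, sigma) are pooled over all voxels of the
  training cohort per modality and *transferred* frozen to validation —
  re-estimating them on validation would leak information and hide scanner
  shift. The published transfer constants (T1: 0.1904/0.2313, T2:
  0.2009/0.2448) are accepted as config overrides. Z-scoring uses the whole
  volume, not the tumor mask; equalization likewise precedes any mask use.

## Radiomics features

Per modality, derived images are: original, Laplacian-of-Gaussian at σ ∈
{2, 3, 4, 5} mm (σ converted to voxels per axis; truncation radius 8σ so
constants and affine ramps are annihilated to near machine precision), and
the 8 sub-bands (LLL…HHH) of a single-level *undecimated* separable
Coiflet-1 decomposition with the low-pass normalized to unit DC gain
(letter i of the label selects the filter along array axis i). Each derived
image yields first-order statistics and five texture families; shape
features are computed once per modality on the original mask geometry.

Gray levels are discretized to a fixed count of 32 equal-width bins over
the in-mask range (Z-scored inputs make a fixed bin *width* unit-dependent;
32 bins is a common MR radiomics choice, config-overridable). Texture
conventions: GLCM distance 1, 13 unique 3D directions, symmetric, features
angle-averaged over per-direction values; GLRLM runs along the same 13
directions, out-of-mask voxels break runs; GLSZM zones under
26-connectivity; GLDM dependence = neighbors within α = 0 of the center
plus the center itself (26-neighborhood); NGTDM sums |level − mean of
valid in-mask neighbors|. Entropies are base 2. Formulas follow the
standard radiomics reference definitions, and every matrix-based feature is
verified against a naive nested-loop oracle to 1e-12 in the test suite.

Degenerate statistics (GLCM correlation at a single gray level, skewness of
a single voxel) are reported as *undefined with a reason* and excluded from
modeling — never NaN-propagated or silently dropped. The default inventory
is 2308 features per patient (2 modalities × 13 derived images × 88
first-order/texture features + 2 × 10 shape); the reference workflow this
mirrors reports 1197 from a different per-class inventory, and the count
here is manifest-documented rather than forced to match. Volume is the
voxel-count volume; surface area comes from a marching-cubes mesh of the
padded mask, sphericity from the two combined; axis lengths are 4√λ of the
PCA of physical voxel coordinates.

## Prognostic modeling

Blocks are modeled separately and then combined by PI stacking:

1. **VASARI block** — the recoded, reference-level dummy-coded qualitative
   table is screened by univariate Cox (keep Wald p ≤ 0.2), then reduced by
   fast backward elimination (remove the largest Wald p while p > 0.2,
   refitting each step).
2. **Radiomics block** — features are Z-scored with training-frozen
   parameters, screened the same way, then pairwise Spearman elimination at
   |rs| > 0.85 (strict: a pair exactly at 0.85 is kept). The survivor of a
   violating pair is the one with the smaller univariate Cox p. Candidates
   entering the multivariable fit are capped at half the event count
   (events-per-variable sanity on small cohorts), then backward-eliminated.
3. **Clinical block** — sex, surgery type, age > 70, non-standard adjuvant
   regimen and MGMT status all entered, no elimination.

PI = Σ βᵢxᵢ, centered at the training feature means so stacked baselines
are comparable (PI differences are centering-invariant; no rescaling by
default). Models 4–7 are Cox fits with the component PIs as the only
covariates. Cox fits use Efron tie handling whenever tied event times
exist; without ties the Breslow path is taken (identical likelihood,
several-fold faster), and the univariate screen additionally uses a
dedicated single-covariate Newton solver when all times are distinct —
agreement with the general engine is asserted in the tests. Separation is
detected (runaway or non-finite coefficients, singular information) and
raised with the offending feature named.

Validation diagnostics, all computed with the training model frozen:

* **Harrell's C** per cohort (ties count ½), 95 % CI by patient-level
  bootstrap (500 resamples by default; the CI method is a package choice).
* **Calibration slope** — the frozen PI refit as sole covariate on
  validation; the test of slope = 1 is a likelihood-ratio comparison
  against the offset model. On self-validation the slope is exactly 1 (the
  score equation of the original fit).
* **Misspecification** — the signature's individual features refit on
  validation with the frozen PI as offset; joint LR test that all added
  coefficients are zero. Under the null its p-value is uniform (checked by
  KS over 200 simulated validations).
* **Risk split** — the 75th percentile of the *training* PI, frozen, splits
  both cohorts; log-rank tests the split, and group curves are plotted as
  observed KM (solid) next to model-predicted curves (dashed): per patient
  S(t) = exp(−H₀(t)·e^PI) with H₀ the Breslow baseline from training,
  averaged over the group.
* **Volume surrogacy** — Spearman correlation of each selected radiomics
  feature against mask volume; **cross-block correlation** uses
  point-biserial r for binary-vs-continuous pairs, Spearman for continuous
  pairs and phi for binary pairs.

## Predictive modeling

Per marker (MGMT methylation, EGFR amplification, IDH1 mutation; patients
with missing labels excluded): correlation elimination at |rs| > 0.85
dropping the member with the lower univariate ROC AUC (folded to
max(AUC, 1−AUC) so discrimination is direction-agnostic; ties break
lexicographically), training-cohort Z-scoring, a stratified 70/30 split,
cumulative Gini importance over random-forest fits with uniformly sampled
hyperparameters (trees ∈ [20, 300], depth ∈ [2, 6]) to select the top 20
features, then a randomized search over XGBoost, random forest and logistic
regression (learning rate and L2 strength log-uniform over [0.01, 0.3] and
[1e−3, 10]; logistic C over [1e−3, 1e3] — ranges beyond the two published
ones are package defaults). The top five candidates by test AUC are
re-evaluated over 10 fresh stratified splits (guarding the "lucky split"),
the best mean wins, is refit on the full training-center cohort, frozen,
and applied to the external cohort. The VASARI arm can be pinned to a
family per marker (logistic regression for MGMT by default). The VASARI and
radiomics arms are ensembled by element-wise averaging of predicted
probabilities. AUCs carry percentile 95 % CIs from 100 patient-level
bootstrap resamples (resamples missing a class are redrawn and logged);
with only 100 resamples the percentile interval undercovers slightly
(measured ≈ 93 % at nominal 95 %), a property of the prescribed iteration
count rather than of the implementation. Feature-level heterogeneity uses
two-sided Mann–Whitney tests with Bonferroni correction (multiplied by the
feature count, capped at 1).

Top-20 selection is re-run for each repeated split in the full pipeline
(the alternative — freezing the selection once — is a config flag);
importance uses Gini impurity.

## Orchestration and reproducibility

The pipeline runs as stages (simulate → extract → prognostic → predictive →
report) from a YAML config; a single master seed deterministically derives
every inner seed, and the run manifest records a SHA-256 per CSV/JSON
artifact — two runs with the same config are bit-identical. The expensive
extraction stage is cached on disk keyed by a hash of the relevant config
sections. The `glioscan` CLI exposes the stages; the numbered scripts under
`analysis/` are the same stages as a narrated study.

## Evaluation sizes

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen once: oracle equivalence on 50 random 5×5×3 images; N4 improvement
on 50 biased phantoms; Cox recovery at n = 2000; misspecification null
calibration over 200 simulated validations of n = 150; selection recovery
with 3 planted + 20 noise features at n = 1000 (100 seeds in the tests, 60
in the acceptance script); stacking comparison over 20 train/validation
pairs (n = 1000/500); top-20 recovery over 10 seeds with 50 importance
fits; bootstrap coverage over 200 repetitions; and a 24/12-patient demo
study (16/8 in the quickest smoke tests) for the end-to-end determinism
check.

## Known limitations

* Synthetic anatomy is geometric; no registration, motion, or Rician noise.
* The per-class feature inventory differs from any specific extraction
  tool's count; the manifest is the source of truth.
* "Fast backward" elimination refits at every step (the single-fit
  df-approximation is not reproduced; the selection direction is the same).
* The exact VASARI recoding cut-points of the reference workflow are not
  public; the shipped recoding map is a documented substitute, and a
  user-supplied JSON map replaces it.
* Absolute-risk prediction is limited to group-averaged predicted survival
  curves; no competing risks or time-varying covariates.
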