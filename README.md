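# glioscan

Integrated qualitative and quantitative MRI analysis for glioblastoma
(GBM). `glioscan` builds prognostic models for overall survival from three
feature blocks — radiologist-scored **VASARI** qualitative features,
**radiomics** features computed from co-registered T1+Gd / T2 volumes with
tumor delineations, and **clinical** covariates — and predictive models for
the molecular markers *MGMT* methylation, *EGFR* amplification and *IDH1*
mutation. It is aimed at imaging researchers who want a tested, fully
reproducible implementation of this multi-block workflow; because patient
cohorts of this kind cannot be redistributed, the package includes a
synthetic multi-scanner cohort generator with recorded ground truth, so
the entire study runs — and is validated by parameter recovery — without
any patient data.

## The models

**Prognostic.** Each block b yields a Cox proportional-hazards model with
coefficients β_b over its features x; its prognostic index is the linear
risk score

    PI_b = Σ_i β_bi · x_i        (centered at training means)

Radiomics features are Z-scored with training-frozen parameters, screened
by univariate Cox (keep Wald p ≤ 0.2), de-correlated (drop one of any pair
with Spearman |r_s| > 0.85) and reduced by backward elimination (removal
α = 0.2); VASARI features are screened and backward-eliminated; clinical
covariates are all entered. Combined models 4–7 are Cox fits with the
component PIs as the only covariates (PI stacking). External validation is
multi-step: Harrell's C per cohort with bootstrap CIs, the calibration
slope of the frozen PI on the validation cohort with a likelihood-ratio
test of slope = 1, a joint misspecification test of the signature features
with the PI as offset, and a Kaplan–Meier risk split at the frozen 75th
percentile of the training PI with observed and model-predicted curves.

**Predictive.** Per marker and feature block: correlation elimination
keeping the higher univariate ROC AUC, a stratified 70/30 split, top-20
selection by cumulative random-forest importance over randomly sampled
hyperparameters (trees ∈ [20, 300], depth ∈ [2, 6]), randomized search over
XGBoost / random forest / logistic regression, repeated-split re-evaluation
of the top five, and a probability-averaging ensemble of the VASARI and
radiomics arms, with 100-iteration bootstrap AUC confidence intervals.

**Radiomics.** First-order, shape, and GLCM / GLRLM / GLSZM / GLDM / NGTDM
texture features on the original image, four Laplacian-of-Gaussian scales
(σ = 2–5 mm) and eight undecimated Coiflet-1 wavelet sub-bands, per
modality — implemented from scratch on NumPy and verified against naive
brute-force oracles to 1e-12. Preprocessing: resampling (bicubic in-plane),
N4 bias-field correction, global histogram equalization, and Z-score
standardization transferred frozen from the training cohort.

## Worked example

The numbered scripts under `analysis/` run the study end to end (they share
an output directory and reuse cached stages):

```bash
python analysis/01_simulate_cohorts.py --seed 1 --out-dir results/study
python analysis/02_extract_features.py --seed 1 --out-dir results/study
python analysis/03_prognostic_models.py --seed 1 --out-dir results/study
python analysis/04_predict_markers.py  --seed 1 --out-dir results/study
python analysis/05_report.py           --seed 1 --out-dir results/study
```

which prints (seed 1):

```
training cohort: n=24, events=18, median OS=18.5 months
validation cohort: n=12, events=11, median OS=14.2 months
extracted 2308 features x 24 training patients
frozen Z-score transfer: t1 mu=0.5000 sigma=0.2887, t2 mu=0.5000 sigma=0.2887
Harrell's C-index (train / validation):
  model1_vasari                0.659 / 0.662
  model2_radiomics             0.791 / 0.569
  model3_clinical              0.784 / 0.806
  model4_vasari_radiomics      0.791 / 0.569
  model5_vasari_clinical       0.827 / 0.796
  model6_radiomics_clinical    0.848 / 0.833
  model7_integrated            0.877 / 0.870
integrated model: calibration slope 0.91 (p=0.81 vs slope=1), misspecification p=0.69, KM split log-rank p (val)=0.0014
MGMT: validation AUC (95% CI)
  ensemble   0.533 (0.145-0.862)
  radiomics  0.433 (0.103-0.777) [logistic_regression]
  vasari     0.600 (0.126-0.929) [logistic_regression]
```

Reading this: the two synthetic cohorts differ in scanner mixture and
survival (the generator plants risk in tumor volume, edema extent and
adjuvant regimen). Single-block models validate unevenly — radiomics alone
drops from C = 0.79 in training to 0.57 externally — while the integrated
model 7 (all three PIs stacked) is both the most discriminative and the
most stable (0.877 → 0.870), with a calibration slope near 1 (no evidence
of overfitting), no evidence of misspecification, and a significant
high/low-risk Kaplan–Meier split on the external cohort at the frozen
training threshold. The MGMT prediction, with only 12 external patients,
is uninformative (CIs spanning 0.5) — exactly the small-validation-cohort
behavior this workflow is designed to expose. Z-score parameters of 0.5 and
0.289 are the mean and sd of a histogram-equalized (uniform) image, as
expected. Figures (C-index forest plot, observed-vs-predicted KM curves,
AUC chart) land under `results/study/report/`.

The same pipeline is scriptable as a CLI (`glioscan run-all --seed 1
--out-dir results/study`, plus per-stage subcommands) and configurable via
YAML; see `docs/methods.md` for the model details and every default.

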