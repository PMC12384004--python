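# dlcoradiomics

CT-radiomics pipeline for predicting abnormal lung diffusing capacity
(DLCO) from texture features of healthy lung parenchyma on two
respiratory phases of a 4DCT scan.

The diffusing capacity of the lungs for carbon monoxide, reported as a
percent of the predicted value and dichotomized as normal within 75–140%,
is a routine pulmonary-function endpoint for lung-cancer patients treated
with stereotactic body radiotherapy.  This package implements, end to
end, a radiomics analysis of that endpoint for researchers in
quantitative imaging and radiation oncology:

- **Preprocessing** — histogram-based intensity normalization, absolute
  discretization (binWidth 25 HU), GTV expansion (0.5 mm) and
  lungs-minus-GTV mask algebra;
- **Filter bank** — single-level undecimated 3-D wavelet subbands
  (LLL…HHH), Laplacian of Gaussian at physical scales, gradient
  magnitude, and square / square-root / logarithm / exponential intensity
  transforms;
- **Features** — first-order statistics plus GLCM Correlation and Imc1,
  GLDM Low Gray Level Emphasis and GLSZM Size Zone Non-Uniformity
  Normalized, on every filtered image, with canonical
  `<filter>_<class>_<Name>` naming, for Phase 0 (max inhalation),
  Phase 50 (max exhalation), and their per-feature difference (Δ phase);
- **Feature selection** — near-zero-variance screening, |Spearman| > 0.95
  pruning, then iterative correlation clustering at |ρ| > 0.75 keeping,
  per cluster, the feature most associated with the abnormal-DLCO label
  (two-sided Wilcoxon rank-sum);
- **Radiomic score** — LASSO logistic coefficients on the selected
  standardized features; the score of a patient is Σᵢ βᵢ·xᵢ;
- **Evaluation** — thirteen predictive models ({radiomic,
  clinical-radiomic} × {Phase 0, Phase 50, Δ} × {baseline,
  post-treatment} plus a clinical-only baseline model), each scored by
  repeated stratified 3-fold cross-validated AUC with all learning steps
  confined to training folds;
- **Synthetic cohort generator** — paired-phase volumes whose parenchymal
  texture differs by DLCO class with a tunable effect size, respiratory
  compression between phases, lesions inside the lungs, and clinical
  covariates (CCI, COPD, smoking) coupled to the label — so the whole
  chain is testable without any clinical imaging data.

See `docs/methods.md` for the model, its assumptions and every default.

## Worked example

```python
import dlcoradiomics as dr

# a 60-patient synthetic cohort with a strong planted texture effect
cfg = dr.CohortConfig(n_patients=60, seed=11, texture_effect=2.0,
                      clinical_effect=1.5)
patients, clinical = dr.generate_cohort(cfg)

t0   = dr.extract_cohort_features(patients, "phase0")
t50  = dr.extract_cohort_features(patients, "phase50")
model = dr.DlcoRadiomicsModel.from_tables(
    t0, t50, dr.delta_features(t0, t50), clinical, reps=10,
)
results = model.fit(seed=5)
frame = results.to_frame()
print(frame[frame.endpoint == "baseline"][["model", "median_auc"]])
```

prints (abridged):

```
                                 model  median_auc
0             radiomic_phase0_baseline    1.000000
2            radiomic_phase50_baseline    0.999389
4              radiomic_delta_baseline    1.000000
6    clinical-radiomic_phase0_baseline    1.000000
8   clinical-radiomic_phase50_baseline    0.999389
10    clinical-radiomic_delta_baseline    1.000000
12              clinical_none_baseline    0.691697
```

With `texture_effect=2.0` the parenchymal gray-level structure separates
the classes almost perfectly, so every radiomic model saturates at
AUC ≈ 1.0 while the clinical-only model (CCI) reaches ≈ 0.69 — the
qualitative ordering the design is built to detect.  At
`texture_effect=0` the same code yields median AUCs at chance (≈ 0.5) for
every model; `results.summary()` prints the full thirteen-model table
with IQRs and the per-phase selected features.

The same run is available from the shell:

```bash
dlcorad simulate --seed 7 --n 10 --outdir cohort/       # NRRD + CSV
dlcorad run --config pipeline.yaml                      # full pipeline
```

where `pipeline.yaml` names either a synthetic cohort or an `input_dir`
of NRRD/NIfTI volumes plus a clinical CSV, and the run directory receives
feature tables, the selection audit trail, per-model AUCs (JSON/CSV) and
a Markdown report.

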