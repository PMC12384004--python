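# Methods

`dlcoradiomics` re-implements, as a tested and reusable pipeline, a
CT-radiomics analysis that predicts abnormal lung diffusing capacity
(DLCO, dichotomized at 75–140% of predicted) from texture features of
healthy lung parenchyma imaged at two respiratory phases of a 4DCT scan.
Because no clinical imaging cohort ships with the package, a synthetic
cohort generator with a controllable planted signal stands in for the
data; everything downstream of the generator is the analysis itself.

## Processing model

Per patient and respiratory phase (Phase 0 = maximum inhalation,
Phase 50 = maximum exhalation):

1. **Region definition.** The tumor masks (GTVs) are geometrically
   expanded by a physical margin (default 0.5 mm, Euclidean in
   millimetres with anisotropic spacing respected) and subtracted from
   the lung mask.  All features are computed on this lungs-minus-GTV
   parenchyma region.  At a typical CT resolution of 1×1×2.5 mm the
   0.5 mm expansion is a no-op — no neighboring voxel center lies within
   the margin — but the operation is implemented generically via a
   Euclidean distance transform and behaves correctly at any resolution.
2. **Intensity normalization (optional, off by default for calibrated
   HU).**  Histogram matching against a reference scan: the input's
   values at a fixed set of anchor percentiles, default
   (1, 5, 25, 50, 75, 95, 99), are mapped piecewise-linearly onto the
   reference's values at the same percentiles, extrapolating with the
   terminal-segment slope.  The anchor set avoids the extreme order
   statistics so isolated voxels cannot skew the map.  The transform is
   monotone by construction; a constant input, for which no map exists,
   is passed through unchanged with a warning.
3. **Filter bank.**  Derived images: the original; 8 subbands of a
   single-level undecimated separable 3-D wavelet transform (default
   family `coif1`); Laplacian-of-Gaussian at physical scales (default
   2.0 and 4.0 mm); gradient magnitude (central differences over physical
   spacing); and monotone intensity transforms (square, square root,
   logarithm, exponential) with domain-respecting shifts and rescaling to
   the input magnitude range.  The wavelet transform is computed by
   circular convolution in the Fourier domain with the analysis taps
   scaled by 1/√2 per axis, which makes the 8-band analysis exactly
   energy-preserving for orthogonal families and invertible by its
   adjoint; the LoG kernels are DC-corrected so a constant volume maps
   exactly to zero despite kernel truncation.
4. **Features.**  On each derived image restricted to the region:
   first-order statistics (maximum, median, mean, minimum, range,
   population variance, skewness, energy) of the continuous intensities,
   and — after absolute discretization of the filtered intensities with a
   fixed bin width (default 25 HU, referenced to the in-region minimum) —
   GLCM Correlation and Imc1 (13 unique 3-D directions at Chebyshev
   distance 1, symmetrized, counts summed across directions before
   normalization), GLDM Low Gray Level Emphasis (dependence α = 0,
   26-neighborhood), and GLSZM Size Zone Non-Uniformity Normalized
   (26-connected equal-level zones).  Feature names follow the
   `<filter>_<class>_<Name>` convention (e.g.
   `wavelet-HHH_glcm_Correlation`).  Degenerate single-gray-level regions
   take Correlation = 1 and Imc1 = 0, the conventions of the widely used
   extraction tools.  Δ-phase features are Phase 0 minus Phase 50,
   element-wise; the sign is a fixed convention and downstream models are
   invariant to it up to coefficient sign.

Re-using the same absolute bin width on each filtered image's own range
(rather than per-image adaptive bin counts) keeps a single discretization
rule across the bank; high-pass subbands with narrow ranges consequently
have few gray levels, which is accepted as part of the convention.

## Feature selection

Applied per phase design (Phase 0, Phase 50, Δ), with the binary
abnormal-DLCO label:

1. near-zero-variance screening (drop constants and columns with
   most-common/second-most-common frequency ratio > 19 while the
   distinct-value fraction is < 0.1 — the widely used caret thresholds);
2. redundancy pruning: among any pair with |Spearman| > 0.95 the member
   with the weaker label association (larger two-sided Wilcoxon rank-sum
   p-value) is dropped, greedily by descending correlation;
3. iterative correlation clustering: connected components of the
   |Spearman| > 0.75 graph; per component the smallest-p feature
   survives; repeat until no edges remain.  Connected components are the
   parameter-free reading of "clustering by correlation" and make the
   stopping rule exact: termination is guaranteed because every
   iteration with at least one edge strictly reduces the feature count,
   and the surviving set satisfies max pairwise |Spearman| below the
   threshold by construction.

Absolute correlation is used at both thresholds (anti-correlated features
are equally redundant), and every tie — equal p-values, equal
correlations — is broken by the lexicographically smallest feature name so
runs are bit-reproducible under column permutations.

## Radiomic score and the thirteen models

On standardized (training-fold mean/SD) selected features, an L1-penalized
logistic regression yields one coefficient per feature; the penalty is
chosen by internal stratified cross-validated deviance minimum (3 inner
folds, 8 penalty values log-spaced over 10^±2.5) and the fit is seeded.
The radiomic score of a patient is Σ coefficient × feature value, with no
intercept; downstream logistic models refit an intercept.

The evaluation design is thirteen models: {radiomic, clinical-radiomic} ×
{Phase 0, Phase 50, Δ} × {baseline, post-treatment endpoint} plus one
clinical-only model at baseline.  The clinical component defaults to the
single covariate CCI (Charlson Comorbidity Index); a config list can widen
it.  Post-treatment endpoint models reuse the baseline-phase imaging
features, since imaging is acquired at simulation only.

Each model is scored by repeated stratified 3-fold cross-validation
(default 100 repetitions; fewer in the bundled test/acceptance runs).
Within every training fold — and only there — the full learned pipeline
runs: near-zero-variance screening, standardization, correlation pruning,
iterative clustering, LASSO score fit, and the final logistic model; the
held-out fold is scored with the training fold's parameters.  Out-of-fold
predicted probabilities are pooled into one AUC per repetition, and the
median and IQR across repetitions are reported.  Stratified folds are used
because the post-treatment minority class can be small.  AUC is the
rank-based estimator (ties counted ½).

Univariate statistics mirror standard clinical reporting: Wilcoxon
rank-sum for continuous covariates (exact when both groups have n ≤ 10
and no ties, tie-corrected normal approximation otherwise, no continuity
correction); Pearson chi-square for categorical covariates, switching to
Fisher's exact test for 2×2 tables with any cell below 5; Wilcoxon
signed-rank (zeros dropped; exact for ≤ 25 non-zero untied pairs) for the
baseline-vs-post DLCO comparison.  The DLCO normality interval 75–140% is
inclusive at both boundaries.

## Synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes, and nothing more:

- **Parenchyma**: a Gaussian random field — white noise smoothed with a
  Gaussian kernel, rescaled to a 60 HU marginal SD around −850 HU.  The
  abnormal class gets a longer correlation length (base 1.2 voxels plus
  0.5 voxels per unit `texture_effect`) and an additional negatively
  skewed low-intensity component (15 HU per unit effect), so gray-level
  co-occurrence correlation and low-gray-level statistics separate the
  classes; at `texture_effect = 0` the classes are exactly exchangeable.
  Each patient's realized smoothing length (with N(0, 0.15) jitter) is
  recorded as `latent_texture`, the oracle covariate used by calibration
  tests.
- **Anatomy**: an ellipsoidal lung (semi-axes 42% of the physical grid
  extent) in a soft-tissue body (+30 HU); lesions are +20 HU spheres
  placed uniformly inside the lung, radius 4–10 mm, 1–3 per patient, so
  the lungs-minus-GTV subtraction is always exercised.  Configurations
  whose largest lesion cannot fit the lung are rejected.
- **Phases**: Phase 50 is the Phase 0 tissue field compressed
  craniocaudally (slice axis, factor 0.85 about the volume center,
  linear interpolation); both phases then receive independent Gaussian
  acquisition noise (SD 20 HU), so Δ-features are non-zero and carry
  class signal whenever `texture_effect > 0`.  Masks are shared between
  phases.
- **Clinical**: CCI ~ Poisson(2 + `clinical_effect`·abnormal); COPD and
  smoking flags weakly coupled to the label through the same knob; age ~
  N(72, 8) clipped to [40, 90].
- **DLCO**: baseline percent-predicted from truncated normals (normal
  class N(95, 12) on [75, 140]; abnormal N(60, 12) on [20, 75)); the
  label is always re-derived from the 75–140% rule so value and label
  cannot disagree.  A fraction (default 0.6) of patients receives a
  post-treatment value, baseline minus |N(8, 6)| (floored at 20%), which
  can flip baseline-normal patients to post-abnormal.

Defaults: 48×48×32 voxels at 1×1×2.5 mm, 40% abnormal.  The abnormal
fraction, effect sizes and noise levels are conventions chosen to resemble
a thoracic SBRT population; they are not estimates fitted to any dataset.

What the generator deliberately does **not** model: realistic lung
anatomy, deformable respiratory motion, scanner reconstruction kernels,
lesion texture, or correlated clinical covariates.  Passing tests
therefore demonstrate that the pipeline recovers the class structure it is
pointed at and stays calibrated under the null — not that any particular
AUC is attainable on clinical data.  Per-model AUCs are cohort-specific
by nature; the package's own evaluation numbers are whatever the tests
and `scripts/acceptance.py` compute at run time on its synthetic cohorts.

## Numerical choices and degenerate inputs

- Discretization: `level = floor(x/W) − floor(min/W) + 1`, so levels are
  invariant to shifting all intensities by exact multiples of W.
- Wavelet boundary handling is circular (exact adjoint inverse); LoG uses
  nearest-edge padding with zero-sum kernels; gradient uses one-sided
  differences at volume faces.
- Post-treatment models require at least k patients per class to
  stratify; violations raise instead of silently degrading.
- A LASSO that shrinks every coefficient to zero yields a constant score
  and chance-level AUC — the correct null behavior, not an error.
- Spearman correlations involving constant columns are defined as 0
  (constants are redundant with nothing and are screened out earlier).

## Problem sizes in the bundled checks

The test suite and the acceptance script regenerate all cohorts from
scratch.  The calibration and signal-recovery checks use 200-patient
cohorts at the default grid (the acceptance script uses 120 patients and
fewer CV repetitions); the 20-seed selection-recovery check uses
40-patient cohorts on a 32×32×20 grid with the original+wavelet filter
subset.  These sizes are the package's own choice of a desk-scale
experiment: large enough that null AUC sampling noise (SD ≈ 0.03–0.04)
sits well inside the asserted tolerances, small enough to run routinely.

## Known limitations

- LBP2D/LBP3D filters and shape, GLRLM and NGTDM feature families are out
  of scope; the implemented families cover the features this analysis
  design selects plus their standard companions.
- The histogram normalization's anchor percentiles and region of support
  are package conventions; both are configurable.
- Whether GLCM directions should be pooled by sum or average is not
  specified anywhere; summing is the default and a config switch exposes
  averaging.
- The synthetic post-treatment endpoint inherits its predictability from
  the baseline label plus an independent reduction, so post-endpoint AUCs
  on synthetic data are intrinsically weaker than baseline ones.
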