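"""DLCO classification, LASSO radiomic score, and repeated-CV evaluation.

The evaluation design mirrors the clinical study layout: thirteen
predictive models — {radiomic, clinical-radiomic} x {Phase 0, Phase 50,
Δ Phase} x {baseline, post-treatment endpoint} (12 models) plus a single
clinical-only model at baseline — each scored by repeated stratified
3-fold cross-validated AUC.

Inside every training fold, and only there, the full learned pipeline is
re-run: near-zero-variance screening, feature standardization,
high-correlation pruning, iterative correlation clustering, L1-penalized
(LASSO) logistic fit of the radiomic score, and the final logistic model
combining score and clinical covariates.  The held-out fold is scored with
the training fold's parameters, so cross-validation estimates carry no
information leakage.

The radiomic score of a patient is the sum over selected features of
feature value times LASSO coefficient (no intercept); downstream logistic
models refit an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .selection import (
    SelectionConfig,
    iterative_cluster_select,
    near_zero_variance_filter,
    prune_high_correlation,
    rank_sum_pvalues,
)

__all__ = [
    "classify_dlco",
    "ScoreModel",
    "fit_lasso_logistic",
    "radiomic_score",
    "ModelSpec",
    "build_model_matrix",
    "auc",
    "CVResult",
    "EvaluationData",
    "repeated_kfold_auc",
    "paired_wilcoxon_signed_rank",
    "clinical_association_table",
    "DlcoRadiomicsModel",
    "DlcoRadiomicsResults",
]

DLCO_NORMAL_RANGE = (75.0, 140.0)

PHASE_DESIGNS = ("phase0", "phase50", "delta")


def classify_dlco(dlco_pct: float) -> str:
    """Dichotomize a percent-predicted DLCO: normal iff within 75–140%.

    Boundaries are inclusive.  Raises for non-positive values.
    """
    if dlco_pct <= 0:
        raise ValueError(f"DLCO percent-predicted must be positive, got {dlco_pct}")
    lo, hi = DLCO_NORMAL_RANGE
    return "normal" if lo <= dlco_pct <= hi else "abnormal"


def dlco_abnormal(dlco_pct) -> np.ndarray:
    """Vectorized binary abnormal indicator under the 75–140% rule."""
    v = np.asarray(dlco_pct, dtype=float)
    if np.any(v[~np.isnan(v)] <= 0):
        raise ValueError("DLCO percent-predicted must be positive")
    lo, hi = DLCO_NORMAL_RANGE
    return ~((v >= lo) & (v <= hi))


# ---------------------------------------------------------------------------
# LASSO radiomic score


@dataclass(frozen=True)
class ScoreModel:
    """Selected features with their LASSO coefficients (no intercept).

    ``center``/``scale`` record the training-fold standardization the
    coefficients were fit under; :meth:`score_frame` applies them before
    the weighted sum, :func:`radiomic_score` is the raw weighted sum.
    """

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    penalty_lambda: float
    center: tuple[float, ...] = ()
    scale: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.penalty_lambda <= 0:
            raise ValueError("penalty must be positive")

    def score_frame(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise KeyError(f"feature row is missing {missing}")
        x = table[list(self.feature_names)].to_numpy(dtype=float)
        if self.center:
            x = (x - np.asarray(self.center)) / np.asarray(self.scale)
        return x @ np.asarray(self.coefficients)


def radiomic_score(feature_row: dict | pd.Series, model: ScoreModel) -> float:
    """Sum of feature value times coefficient over the model's features."""
    total = 0.0
    for name, coef in zip(model.feature_names, model.coefficients):
        if name not in feature_row:
            raise KeyError(f"feature row is missing {name!r}")
        total += float(coef) * float(feature_row[name])
    return total


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: tuple[str, ...],
    seed: int,
    penalty_lambda: float | None = None,
    n_lambdas: int = 8,
) -> ScoreModel:
    """L1-penalized logistic regression on standardized features.

    When ``penalty_lambda`` is None the penalty is chosen by internal
    stratified cross-validated deviance minimum (seeded, deterministic);
    otherwise the given value is used directly.  ``penalty_lambda`` is the
    reciprocal of scikit-learn's ``C``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each class")
    if penalty_lambda is not None:
        est = LogisticRegression(
            l1_ratio=1, C=1.0 / penalty_lambda, solver="liblinear",
            random_state=seed, max_iter=2000,
        )
        est.fit(X, y)
        coefs = est.coef_[0]
        lam = float(penalty_lambda)
    else:
        inner = min(3, int(counts.min()))
        cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
        est = LogisticRegressionCV(
            l1_ratios=[1], solver="liblinear", Cs=np.logspace(-2.5, 2.5, n_lambdas),
            cv=cv, scoring="neg_log_loss", random_state=seed, max_iter=2000,
            use_legacy_attributes=False,
        )
        est.fit(X, y)
        coefs = est.coef_[0]
        lam = float(1.0 / est.C_)
    return ScoreModel(tuple(feature_names), tuple(float(c) for c in coefs), lam)


# ---------------------------------------------------------------------------
# The thirteen-model design


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the evaluation design."""

    kind: str  # clinical | radiomic | clinical-radiomic
    phase_design: str | None  # phase0 | phase50 | delta | None
    endpoint: str  # baseline | post

    def __post_init__(self) -> None:
        if self.kind not in ("clinical", "radiomic", "clinical-radiomic"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "clinical":
            if self.phase_design is not None:
                raise ValueError("the clinical model has no phase design")
        elif self.phase_design not in PHASE_DESIGNS:
            raise ValueError(f"unknown phase design {self.phase_design!r}")
        if self.endpoint not in ("baseline", "post"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")

    @property
    def name(self) -> str:
        phase = self.phase_design or "none"
        return f"{self.kind}_{phase}_{self.endpoint}"


def build_model_matrix() -> list[ModelSpec]:
    """The thirteen predictive models of the evaluation design.

    {radiomic, clinical-radiomic} x {Phase 0, Phase 50, Δ} x {baseline,
    post} plus a single clinical-only baseline model.
    """
    specs = [
        ModelSpec(kind, phase, endpoint)
        for kind in ("radiomic", "clinical-radiomic")
        for phase in PHASE_DESIGNS
        for endpoint in ("baseline", "post")
    ]
    specs.append(ModelSpec("clinical", None, "baseline"))
    return specs


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score of a positive > score of a negative), ties ½."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute an AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Repeated stratified k-fold evaluation


@dataclass(frozen=True)
class CVResult:
    """Per-repetition pooled AUCs with their median and IQR."""

    aucs: tuple[float, ...]
    k: int
    reps: int
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.aucs))

    @property
    def iqr(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.aucs, [25, 75])
        return float(q1), float(q3)

    def to_dict(self) -> dict:
        q1, q3 = self.iqr
        return {
            "median_auc": self.median,
            "iqr": [q1, q3],
            "aucs": list(self.aucs),
            "k": self.k,
            "reps": self.reps,
            "seed": self.seed,
        }


@dataclass
class EvaluationData:
    """Feature tables per phase design plus the clinical table with labels.

    ``features`` maps 'phase0' / 'phase50' / 'delta' to patients x features
    tables indexed by patient_id; ``cohort`` is indexed the same way and
    carries covariates, ``dlco_baseline_pct`` and optional
    ``dlco_post_pct``.
    """

    features: dict[str, pd.DataFrame]
    cohort: pd.DataFrame
    covariates: tuple[str, ...] = ("cci",)

    def endpoint_frame(self, endpoint: str) -> tuple[pd.DataFrame, np.ndarray]:
        col = "dlco_baseline_pct" if endpoint == "baseline" else "dlco_post_pct"
        rows = self.cohort[self.cohort[col].notna()]
        y = dlco_abnormal(rows[col].to_numpy())
        return rows, y.astype(int)


def _fold_pipeline(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    x_test: pd.DataFrame,
    selection: SelectionConfig,
    seed: int,
):
    """Training-fold selection + LASSO score; returns train/test scores."""
    table = near_zero_variance_filter(x_train, selection)
    center = table.mean()
    scale = table.std(ddof=0).replace(0.0, 1.0)
    table_std = (table - center) / scale
    pvals = rank_sum_pvalues(table_std, y_train)
    pruned = prune_high_correlation(table_std, y_train, selection.prune_rho, pvalues=pvals)
    sel = iterative_cluster_select(pruned, y_train, selection, pvalues=pvals)
    feats = list(sel.selected)
    score_model = fit_lasso_logistic(
        table_std[feats].to_numpy(), y_train, tuple(feats), seed
    )
    test_std = (x_test[table.columns] - center) / scale
    train_scores = table_std[feats].to_numpy() @ np.asarray(score_model.coefficients)
    test_scores = test_std[feats].to_numpy() @ np.asarray(score_model.coefficients)
    return train_scores, test_scores, sel, score_model


def _logistic_prob(train_X, y_train, test_X, seed: int) -> np.ndarray:
    est = LogisticRegression(C=np.inf, max_iter=5000, random_state=seed)
    est.fit(train_X, y_train)
    return est.predict_proba(test_X)[:, 1]


def repeated_kfold_auc(
    spec: ModelSpec,
    data: EvaluationData,
    k: int = 3,
    reps: int = 100,
    seed: int = 0,
    selection: SelectionConfig = SelectionConfig(),
) -> CVResult:
    """Repeated stratified k-fold CV AUC for one model of the design.

    Per repetition the cohort is shuffled into k stratified folds; per fold
    the entire learned pipeline runs on the training folds only and scores
    the held-out fold; the out-of-fold predictions are pooled into one AUC
    per repetition.
    """
    rows, y = data.endpoint_frame(spec.endpoint)
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError("too few patients in a class to stratify into k folds")
    ids = rows.index
    feature_table = None
    if spec.kind != "clinical":
        feature_table = data.features[spec.phase_design].loc[ids]
    covs = rows[list(data.covariates)].to_numpy(dtype=float)

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(reps)]
    aucs = []
    for rep_seed in rep_seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        pooled_scores = np.zeros(len(y))
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            y_tr = y[train_idx]
            design_tr, design_te = [], []
            if spec.kind != "clinical":
                tr_scores, te_scores, _, _ = _fold_pipeline(
                    feature_table.iloc[train_idx],
                    y_tr,
                    feature_table.iloc[test_idx],
                    selection,
                    rep_seed,
                )
                design_tr.append(tr_scores[:, None])
                design_te.append(te_scores[:, None])
            if spec.kind != "radiomic":
                design_tr.append(covs[train_idx])
                design_te.append(covs[test_idx])
            X_tr = np.hstack(design_tr)
            X_te = np.hstack(design_te)
            pooled_scores[test_idx] = _logistic_prob(X_tr, y_tr, X_te, rep_seed)
        aucs.append(auc(pooled_scores, y))
    return CVResult(tuple(aucs), k, reps, seed)


# ---------------------------------------------------------------------------
# Univariate statistics


def paired_wilcoxon_signed_rank(baseline, post) -> float:
    """Two-sided Wilcoxon signed-rank p for paired values.

    Zero differences are dropped (Wilcoxon's convention); if all
    differences are zero the test is vacuous and p = 1.  Exact for n <= 25
    non-zero pairs, normal approximation beyond.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if baseline.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    diffs = baseline - post
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    method = "exact" if (diffs.size <= 25 and np.unique(np.abs(diffs)).size == diffs.size) else "approx"
    res = stats.wilcoxon(diffs, alternative="two-sided", method=method)
    return float(res.pvalue)


def clinical_association_table(
    cohort: pd.DataFrame,
    label: np.ndarray,
    variables: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-covariate association with the abnormal-DLCO label.

    Continuous covariates use the Wilcoxon rank-sum test; categorical ones
    Pearson's chi-square, switching to Fisher's exact test for 2x2 tables
    with any small (< 5) cell, the usual clinical-reporting convention.
    """
    label = np.asarray(label).astype(bool)
    if label.all() or not label.any():
        raise ValueError("label is degenerate: need both classes")
    if variables is None:
        variables = tuple(
            c for c in cohort.columns
            if c not in ("patient_id", "dlco_baseline_pct", "dlco_post_pct")
        )
    records = []
    for var in variables:
        col = cohort[var]
        distinct = col.nunique(dropna=True)
        if pd.api.types.is_numeric_dtype(col) and distinct > 5:
            a = col[label].to_numpy(dtype=float)
            b = col[~label].to_numpy(dtype=float)
            if np.ptp(np.concatenate([a, b])) == 0:
                p, test = 1.0, "wilcoxon-rank-sum"
            else:
                p = float(
                    stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                )
                test = "wilcoxon-rank-sum"
        else:
            contingency = pd.crosstab(col, label)
            if contingency.shape[0] < 2:
                p, test = 1.0, "chi-square"
            else:
                chi2, p_chi, _dof, expected = stats.chi2_contingency(
                    contingency, correction=False
                )
                small = (expected < 5).any() or (contingency.to_numpy() < 5).any()
                if small and contingency.shape == (2, 2):
                    p = float(stats.fisher_exact(contingency.to_numpy())[1])
                    test = "fisher-exact"
                else:
                    p, test = float(p_chi), "chi-square"
        records.append({"variable": var, "test": test, "p_value": min(float(p), 1.0)})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Model / Results surface


class DlcoRadiomicsModel:
    """The full 13-model evaluation bound to one cohort's data.

    Parameters
    ----------
    data : EvaluationData
        Phase-wise feature tables plus the clinical table.
    k, reps : int
        Folds and repetitions of the repeated stratified CV.
    selection : SelectionConfig
        Screening and clustering thresholds.
    specs : list of ModelSpec, optional
        Defaults to the full thirteen-model design.
    """

    def __init__(
        self,
        data: EvaluationData,
        k: int = 3,
        reps: int = 100,
        selection: SelectionConfig = SelectionConfig(),
        specs: list[ModelSpec] | None = None,
    ) -> None:
        self.data = data
        self.k = k
        self.reps = reps
        self.selection = selection
        self.specs = list(specs) if specs is not None else build_model_matrix()

    @classmethod
    def from_tables(
        cls,
        phase0: pd.DataFrame,
        phase50: pd.DataFrame,
        delta: pd.DataFrame,
        cohort: pd.DataFrame,
        covariates: tuple[str, ...] = ("cci",),
        **kwargs,
    ) -> "DlcoRadiomicsModel":
        cohort = cohort.set_index("patient_id", drop=False) if "patient_id" in cohort.columns and cohort.index.name != "patient_id" else cohort
        data = EvaluationData(
            {"phase0": phase0, "phase50": phase50, "delta": delta},
            cohort,
            covariates,
        )
        return cls(data, **kwargs)

    def fit(self, seed: int = 0) -> "DlcoRadiomicsResults":
        """Run the repeated-CV evaluation of every model in the design.

        Also fits, on the full cohort per phase design, the descriptive
        selection + LASSO score reported alongside the CV estimates.
        """
        cv_results: dict[str, CVResult] = {}
        for spec in self.specs:
            cv_results[spec.name] = repeated_kfold_auc(
                spec, self.data, self.k, self.reps, seed, self.selection
            )
        full_fit: dict[str, dict] = {}
        rows, y = self.data.endpoint_frame("baseline")
        for phase in PHASE_DESIGNS:
            if phase not in self.data.features:
                continue
            table = self.data.features[phase].loc[rows.index]
            _, _, sel, score_model = _fold_pipeline(
                table, y, table, self.selection, seed
            )
            full_fit[phase] = {
                "selected": list(sel.selected),
                "coefficients": dict(
                    zip(score_model.feature_names, score_model.coefficients)
                ),
                "penalty_lambda": score_model.penalty_lambda,
                "iterations": sel.iterations,
            }
        return DlcoRadiomicsResults(self, cv_results, full_fit, seed)


class DlcoRadiomicsResults:
    """Estimates and diagnostics of a fitted :class:`DlcoRadiomicsModel`."""

    def __init__(self, model, cv_results, full_fit, seed) -> None:
        self.model = model
        self.cv_results: dict[str, CVResult] = cv_results
        self.full_fit: dict[str, dict] = full_fit
        self.seed = seed

    def to_frame(self) -> pd.DataFrame:
        """Median (IQR) CV AUC per model, one row per design cell."""
        rows = []
        for spec in self.model.specs:
            res = self.cv_results[spec.name]
            q1, q3 = res.iqr
            rows.append(
                {
                    "model": spec.name,
                    "kind": spec.kind,
                    "phase_design": spec.phase_design or "",
                    "endpoint": spec.endpoint,
                    "median_auc": res.median,
                    "auc_q1": q1,
                    "auc_q3": q3,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable evaluation table."""
        frame = self.to_frame()
        lines = [
            "Repeated {k}-fold cross-validated AUC ({r} repetitions, seed {s})".format(
                k=self.model.k, r=self.model.reps, s=self.seed
            ),
            "=" * 72,
            f"{'model':<38}{'median AUC':>12}{'IQR':>18}",
            "-" * 72,
        ]
        for _, row in frame.iterrows():
            iqr = f"({row.auc_q1:.3f}-{row.auc_q3:.3f})"
            lines.append(f"{row.model:<38}{row.median_auc:>12.3f}{iqr:>18}")
        lines.append("-" * 72)
        for phase, fit in self.full_fit.items():
            kept = {f: c for f, c in fit["coefficients"].items() if c != 0.0}
            lines.append(f"{phase}: selected {len(fit['selected'])} features, "
                         f"{len(kept)} with non-zero LASSO coefficient")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "k": self.model.k,
            "reps": self.model.reps,
            "cv_results": {name: r.to_dict() for name, r in self.cv_results.items()},
            "full_fit": self.full_fit,
        }
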