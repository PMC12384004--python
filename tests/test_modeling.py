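"""DLCO rule, LASSO score, model matrix, AUC and the CV harness."""

import numpy as np
import pandas as pd
import pytest

from dlcoradiomics.modeling import (
    EvaluationData,
    ModelSpec,
    ScoreModel,
    auc,
    build_model_matrix,
    classify_dlco,
    clinical_association_table,
    dlco_abnormal,
    fit_lasso_logistic,
    paired_wilcoxon_signed_rank,
    radiomic_score,
    repeated_kfold_auc,
)


class TestClassifyDlco:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (75.0, "normal"),
            (140.0, "normal"),
            (95.0, "normal"),
            (74.9, "abnormal"),
            (140.1, "abnormal"),
            (30.0, "abnormal"),
        ],
    )
    def test_normality_rule_sweep(self, value, expected):
        assert classify_dlco(value) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            classify_dlco(0.0)
        with pytest.raises(ValueError):
            classify_dlco(-10.0)

    def test_vectorized_consistency(self, rng):
        values = rng.uniform(30, 160, size=100)
        flags = dlco_abnormal(values)
        for v, f in zip(values, flags):
            assert (classify_dlco(v) == "abnormal") == bool(f)


class TestRadiomicScore:
    # representative Phase-0-style score coefficients as arithmetic inputs
    MODEL = ScoreModel(("glcm_corr", "gldm_lgle"), (-39.20, 57.85), 1.0)

    def test_weighted_sum(self):
        assert radiomic_score({"glcm_corr": 1.0, "gldm_lgle": 0.0}, self.MODEL) == pytest.approx(-39.20)
        assert radiomic_score({"glcm_corr": 0.0, "gldm_lgle": 0.0}, self.MODEL) == 0.0

    def test_linearity(self, rng):
        row = {"glcm_corr": 0.3, "gldm_lgle": 0.1}
        base = radiomic_score(row, self.MODEL)
        row2 = dict(row, gldm_lgle=row["gldm_lgle"] * 2)
        assert radiomic_score(row2, self.MODEL) - base == pytest.approx(57.85 * 0.1)

    def test_missing_feature_rejected(self):
        with pytest.raises(KeyError):
            radiomic_score({"glcm_corr": 1.0}, self.MODEL)


class TestLassoLogistic:
    def _data(self, rng, n=60):
        y = np.arange(n) < n // 2
        X = rng.normal(size=(n, 4))
        X[:, 0] += y * 2.0
        X = (X - X.mean(0)) / X.std(0)
        return X, y.astype(int)

    def test_full_shrinkage_limit(self, rng):
        X, y = self._data(rng)
        m = fit_lasso_logistic(X, y, ("a", "b", "c", "d"), seed=0, penalty_lambda=1e6)
        assert all(c == 0.0 for c in m.coefficients)

    def test_separating_feature_positive_sign(self, rng):
        X, y = self._data(rng)
        m = fit_lasso_logistic(X, y, ("a", "b", "c", "d"), seed=0)
        assert m.coefficients[0] > 0

    def test_deterministic(self, rng):
        X, y = self._data(rng)
        m1 = fit_lasso_logistic(X, y, ("a", "b", "c", "d"), seed=3)
        m2 = fit_lasso_logistic(X, y, ("a", "b", "c", "d"), seed=3)
        assert m1.coefficients == m2.coefficients
        assert m1.penalty_lambda == m2.penalty_lambda

    def test_degenerate_labels_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_lasso_logistic(X, np.ones(10, dtype=int), ("a", "b"), seed=0)


class TestModelMatrix:
    def test_thirteen_models(self):
        specs = build_model_matrix()
        assert len(specs) == 13

    def test_single_clinical_model_at_baseline(self):
        clinical = [s for s in build_model_matrix() if s.kind == "clinical"]
        assert len(clinical) == 1
        assert clinical[0].endpoint == "baseline"
        assert clinical[0].phase_design is None

    def test_no_duplicates_and_full_cross(self):
        specs = build_model_matrix()
        assert len(set(specs)) == 13
        for kind in ("radiomic", "clinical-radiomic"):
            for phase in ("phase0", "phase50", "delta"):
                for endpoint in ("baseline", "post"):
                    assert ModelSpec(kind, phase, endpoint) in specs

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("clinical", "phase0", "baseline")
        with pytest.raises(ValueError):
            ModelSpec("radiomic", None, "baseline")


class TestAuc:
    def test_separation_and_ties(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 5, size=20).astype(float)
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        wins = ties = 0
        for sp in scores[labels]:
            for sn in scores[~labels]:
                wins += sp > sn
                ties += sp == sn
        n_pairs = labels.sum() * (~labels).sum()
        assert auc(scores, labels) == pytest.approx((wins + 0.5 * ties) / n_pairs)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        base = auc(scores, labels)
        for f in (np.exp, lambda x: x**3, lambda x: 2 * x + 7):
            assert auc(f(scores), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


class TestPairedWilcoxon:
    def test_identical_vectors(self):
        assert paired_wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_five_positive_differences(self):
        base = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        post = base - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert paired_wilcoxon_signed_rank(base, post) == pytest.approx(0.0625)

    def test_pvalue_range_under_noise(self, rng):
        for _ in range(20):
            base = rng.normal(size=24)
            post = base + rng.normal(size=24)
            p = paired_wilcoxon_signed_rank(base, post)
            assert 0 < p <= 1


class TestClinicalAssociations:
    def test_identical_covariate_p_one(self):
        cohort = pd.DataFrame({"cci": np.full(20, 3)})
        label = np.arange(20) < 10
        out = clinical_association_table(cohort, label, variables=("cci",))
        assert out.loc[0, "p_value"] == 1.0

    def test_fisher_exact_matches_hypergeometric(self):
        # 2x2 table (10,0 / 0,10): p = 2 / C(20,10)
        cohort = pd.DataFrame({"copd": [1] * 10 + [0] * 10})
        label = np.array([True] * 10 + [False] * 10)
        out = clinical_association_table(cohort, label, variables=("copd",))
        assert out.loc[0, "test"] == "fisher-exact"
        assert out.loc[0, "p_value"] == pytest.approx(2 / 184756, rel=1e-6)

    def test_continuous_uses_rank_sum(self, rng):
        cohort = pd.DataFrame({"age": rng.normal(70, 8, size=40)})
        label = rng.random(40) < 0.5
        label[:2] = [True, False]
        out = clinical_association_table(cohort, label, variables=("age",))
        assert out.loc[0, "test"] == "wilcoxon-rank-sum"


def _toy_eval_data(rng, n=36, informative=True):
    y_values = np.where(rng.random(n) < 0.5, 60.0, 95.0)
    abnormal = y_values < 75
    feats = {}
    for i in range(6):
        col = rng.normal(size=n)
        if informative and i == 0:
            col += abnormal * 3.0
        feats[f"f{i}"] = col
    ids = [f"P{i:03d}" for i in range(n)]
    table = pd.DataFrame(feats, index=ids)
    cohort = pd.DataFrame(
        {
            "patient_id": ids,
            "cci": rng.poisson(2, n),
            "dlco_baseline_pct": y_values + rng.uniform(-5, 5, n),
            "dlco_post_pct": np.nan,
        }
    ).set_index("patient_id", drop=False)
    # keep labels consistent with the drawn class
    cohort["dlco_baseline_pct"] = np.where(abnormal, 60.0, 95.0)
    return EvaluationData({"phase0": table, "phase50": table, "delta": table}, cohort)


class TestRepeatedKfold:
    def test_deterministic_given_seed(self, rng):
        data = _toy_eval_data(rng)
        spec = ModelSpec("radiomic", "phase0", "baseline")
        r1 = repeated_kfold_auc(spec, data, reps=3, seed=11)
        r2 = repeated_kfold_auc(spec, data, reps=3, seed=11)
        assert r1.aucs == r2.aucs

    def test_informative_feature_learned(self, rng):
        data = _toy_eval_data(rng, n=60)
        spec = ModelSpec("radiomic", "phase0", "baseline")
        res = repeated_kfold_auc(spec, data, reps=5, seed=1)
        assert res.median > 0.8
        q1, q3 = res.iqr
        assert q1 <= res.median <= q3
        assert all(0 <= a <= 1 for a in res.aucs)

    def test_too_small_class_rejected(self, rng):
        data = _toy_eval_data(rng, n=8)
        # force a 1-patient minority class
        data.cohort["dlco_baseline_pct"] = [60.0] + [95.0] * 7
        with pytest.raises(ValueError):
            repeated_kfold_auc(ModelSpec("radiomic", "phase0", "baseline"), data, reps=2, seed=0)

    def test_test_fold_label_shuffle_yields_null_auc(self, rng):
        """Leakage canary: destroying the test-side label/feature link must
        drive the CV AUC to chance even with a perfectly informative feature."""
        n = 90
        data = _toy_eval_data(rng, n=n)
        # feature exactly equal to the label: any leak inflates AUC
        y = dlco_abnormal(data.cohort["dlco_baseline_pct"]).astype(float)
        for phase in data.features:
            data.features[phase] = data.features[phase].copy()
            data.features[phase]["f0"] = y
        perm = rng.permutation(n)
        shuffled = data.cohort.copy()
        shuffled["dlco_baseline_pct"] = shuffled["dlco_baseline_pct"].to_numpy()[perm]
        null_data = EvaluationData(data.features, shuffled)
        res = repeated_kfold_auc(
            ModelSpec("radiomic", "phase0", "baseline"), null_data, reps=10, seed=2
        )
        assert abs(res.median - 0.5) <= 0.12
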