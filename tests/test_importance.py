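import numpy as np
import pandas as pd
import pytest

from nucgrade.features import FEATURE_NAMES
from nucgrade.importance import (
    FeatureTable,
    ImportanceReport,
    SelectionRule,
    clinical_selection_rule,
    compute_importance_report,
    load_clinical_importance,
    overall_shap,
    pcc,
    pcc_matrix,
    select_features,
    shap_values,
    single_feature_accuracy,
    stratified_split,
)

from conftest import make_gaussian_table


class TestPCC:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert pcc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_constant_input_maps_to_zero(self):
        assert pcc(np.full(5, 3.0), np.arange(5.0)) == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pcc([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pcc([1.0], [2.0])

    def test_matrix_symmetry_and_duplicate_columns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        t = FeatureTable(pd.DataFrame({"a": a, "b": a.copy(),
                                       "c": rng.normal(size=40),
                                       "k": np.full(40, 2.0)}),
                         np.resize([1, 2], 40))
        M = pcc_matrix(t)
        pd.testing.assert_frame_equal(M, M.T)
        assert M.loc["a", "b"] == pytest.approx(1.0)
        assert M.loc["a", "a"] == 1.0
        assert M.loc["k", "k"] == 0.0  # constant feature
        assert (M.loc["k"] == 0).all()

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(1)
        t = FeatureTable(pd.DataFrame(rng.normal(size=(10_000, 2)),
                                      columns=["a", "b"]),
                         np.resize([1, 2], 10_000))
        assert abs(pcc_matrix(t).loc["a", "b"]) < 0.05


class _AdditiveFactory:
    """Toy model family: f_S(y) = sum of fixed per-feature values over S.

    The subset models ignore the data, so the Shapley value of feature i
    is exactly its own term v_i.
    """

    def __init__(self, values, columns_of):
        self.values = values
        self.columns_of = columns_of

    def __call__(self, X, y):
        cols = self.columns_of(X)
        total = sum(self.values[j] for j in cols)

        class M:
            def predict_proba(self, Xq, _t=total):
                return np.full((np.asarray(Xq).shape[0], 1), _t)

        return M()


def additive_factory(table, values):
    X = table.features.to_numpy()

    def columns_of(Xs):
        return [j for j in range(X.shape[1])
                if Xs.shape[1] and any(np.array_equal(Xs[:, k], X[:, j])
                                       for k in range(Xs.shape[1]))]

    # identify subset columns by matching against the full matrix
    def columns_exact(Xs):
        out = []
        for k in range(Xs.shape[1]):
            for j in range(X.shape[1]):
                if np.array_equal(Xs[:, k], X[:, j]):
                    out.append(j)
                    break
        return out

    return _AdditiveFactory(values, columns_exact)


class TestExactShapley:
    def test_single_feature_collapses_to_one_marginal(self):
        t = make_gaussian_table(20, separation=3.0, seed=0, n_noise=0)
        t = t.select(["sig1"])
        phi = shap_values(t, mode="exact")
        from nucgrade.importance import _SubsetPredictions, default_model_factory
        pred = _SubsetPredictions(t.features.to_numpy(float), t.labels,
                                  default_model_factory())
        expected = pred(frozenset({0})) - pred(frozenset())
        np.testing.assert_allclose(phi[:, 0, :], expected, atol=1e-12)

    def test_additive_model_attributes_each_term_to_its_feature(self):
        rng = np.random.default_rng(2)
        t = FeatureTable(pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"]),
                         np.resize([1, 2], 10))
        values = {0: 0.7, 1: -0.4}
        phi = shap_values(t, model_factory=additive_factory(t, values), mode="exact")
        np.testing.assert_allclose(phi[:, 0, 0], 0.7, atol=1e-12)
        np.testing.assert_allclose(phi[:, 1, 0], -0.4, atol=1e-12)

    def test_efficiency_symmetry_and_null_feature(self):
        rng = np.random.default_rng(3)
        n = 45
        y = np.resize([1, 2, 3], n)
        sig = y + rng.normal(0, 0.5, n)
        t = FeatureTable(pd.DataFrame({
            "sig": sig, "twin": sig.copy(),
            "null": np.zeros(n),  # constant: never changes a standardized fit
        }), y)
        phi = shap_values(t, mode="exact")
        from nucgrade.importance import _SubsetPredictions, default_model_factory
        pred = _SubsetPredictions(t.features.to_numpy(float), t.labels,
                                  default_model_factory())
        full = pred(frozenset(range(3)))
        empty = pred(frozenset())
        np.testing.assert_allclose(phi.sum(axis=1), full - empty, atol=1e-8)
        np.testing.assert_allclose(phi[:, 0, :], phi[:, 1, :], atol=1e-8)
        np.testing.assert_allclose(phi[:, 2, :], 0.0, atol=1e-8)

    def test_exact_mode_caps_feature_count(self):
        t = make_gaussian_table(6, separation=1.0, seed=4, n_noise=11)
        with pytest.raises(ValueError, match="sampled"):
            shap_values(t, mode="exact")

    def test_signal_outranks_noise(self):
        t = make_gaussian_table(40, separation=4.0, seed=5, n_noise=1)
        phi = shap_values(t, mode="exact")
        s = overall_shap(phi, t.feature_names)
        assert s["sig1"] > s["noise1"]
        assert (s >= 0).all()


class TestSampledShapley:
    def test_converges_to_exact(self):
        t = make_gaussian_table(15, separation=2.0, seed=6, n_noise=3)  # |T| = 5
        exact = shap_values(t, mode="exact")
        mads = []
        for n_perm in (40, 400, 4000):
            est = shap_values(t, mode="sampled", n_permutations=n_perm, seed=9)
            mads.append(np.abs(est - exact).mean())
        assert mads[-1] < 0.02
        assert mads[2] < mads[0]

    def test_seed_reproducibility(self):
        t = make_gaussian_table(10, separation=2.0, seed=7, n_noise=1)
        a = shap_values(t, mode="sampled", n_permutations=50, seed=1)
        b = shap_values(t, mode="sampled", n_permutations=50, seed=1)
        np.testing.assert_array_equal(a, b)


class TestSingleFeatureAccuracy:
    def test_label_copy_feature_is_perfect_on_mild_heavy_cohort(self):
        # class balance mirrors clinical cohorts (middle grade prominent);
        # with balanced classes one-vs-all linear scoring masks the middle
        # grade even for a perfectly separating 1-D feature
        rng = np.random.default_rng(8)
        y = np.array([1] * 30 + [2] * 60 + [3] * 30)
        t = FeatureTable(pd.DataFrame({"copy": y.astype(float),
                                       "noise": rng.normal(size=y.size)}), y)
        assert single_feature_accuracy(t, "copy", split_seed=0) == 1.0

    def test_balanced_label_copy_feature_hits_masking_ceiling(self):
        # both outer grades are recovered; the middle grade's fitted
        # indicator line is dominated, capping accuracy at 2/3
        y = np.resize([1, 2, 3], 90)
        t = FeatureTable(pd.DataFrame({"copy": y.astype(float)}), y)
        assert single_feature_accuracy(t, "copy", split_seed=0) == pytest.approx(2 / 3)

    def test_noise_feature_is_chance_level(self):
        rng = np.random.default_rng(9)
        n = 3000
        y = np.resize([1, 2, 3], n)
        t = FeatureTable(pd.DataFrame({"noise": rng.normal(size=n)}), y)
        acc = single_feature_accuracy(t, "noise", split_seed=0)
        assert acc == pytest.approx(1 / 3, abs=0.03)

    def test_constant_feature_gives_majority_rate(self):
        y = np.array([1] * 10 + [2] * 30 + [3] * 60)
        t = FeatureTable(pd.DataFrame({"const": np.zeros(y.size)}), y)
        acc = single_feature_accuracy(t, "const", split_seed=0)
        _, te = stratified_split(y, 0.3, 0)
        majority = np.mean(y[te] == 3)
        assert acc == pytest.approx(majority)


def report_from_shap(shap_map, matrix=None):
    table = pd.DataFrame({"overall_shap": pd.Series(shap_map)})
    return ImportanceReport(table=table, pcc_matrix=matrix)


class TestSelection:
    def test_clinical_values_retain_22_features(self):
        report = load_clinical_importance()
        selected = select_features(report, clinical_selection_rule())
        assert len(selected) == 22
        dropped = set(FEATURE_NAMES) - set(selected)
        assert dropped == {"D-Minimum", "D-Uniformity", "G-Maximum",
                           "G-Minimum", "D-Median"}
        assert selected == [f for f in FEATURE_NAMES if f not in dropped]

    def test_zero_floor_and_no_pairs_is_identity(self):
        report = load_clinical_importance()
        rule = SelectionRule(shap_floor=0.0, redundancy_threshold=1.0)
        assert select_features(report, rule) == list(FEATURE_NAMES)

    def test_duplicated_column_drops_lower_shap_member(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        M = pd.DataFrame(np.ones((2, 2)), index=["hi", "lo"], columns=["hi", "lo"])
        report = report_from_shap({"hi": 0.9, "lo": 0.2}, matrix=M)
        assert select_features(
            report, SelectionRule(shap_floor=0.0, redundancy_threshold=0.95)
        ) == ["hi"]

    def test_exact_tie_drops_raw_statistic_partner(self):
        report = report_from_shap({"G-Minimum": 0.164, "GI-Minimum": 0.164})
        rule = SelectionRule(shap_floor=0.0, resolved_pairs=(("G-Minimum", "GI-Minimum"),))
        assert select_features(report, rule) == ["GI-Minimum"]

    def test_empty_selection_rejected(self):
        report = report_from_shap({"a": 0.01, "b": 0.02})
        with pytest.raises(ValueError, match="empty selection"):
            select_features(report, SelectionRule(shap_floor=1.0))


class TestReportOrchestration:
    def test_report_covers_all_columns_and_classes(self):
        t = make_gaussian_table(25, separation=3.0, seed=11, n_noise=1)
        report = compute_importance_report(t, mode="exact", split_seed=0)
        assert list(report.table.index) == t.feature_names
        for col in ("overall_shap", "pcc_label", "single_feature_acc",
                    "shap_normal", "shap_mild", "shap_severe"):
            assert col in report.table.columns
        assert report.pcc_matrix.shape == (3, 3)
        assert (report.table["overall_shap"] >= 0).all()
        assert report.table["pcc_label"].between(-1, 1).all()
        assert report.table["single_feature_acc"].between(0, 1).all()
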