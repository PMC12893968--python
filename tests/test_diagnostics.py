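"""Statistics layer: contingency tests, location tests, kappa, logistic, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from ulmkit import diagnostics as dx
from ulmkit import phantom


class TestChiSquare:
    @pytest.mark.parametrize("name, expected", [
        ("microcalcification", 6.770),
        ("orientation", 5.554),
        ("histologic_grade", 2.510),
        ("lymph_node_status", 0.888),
        ("area_of_enhancement", 42.933),
        ("mv_distribution", 6.509),
        ("flow_direction", 13.064),
    ])
    def test_reference_tables_reproduce_published_statistics(self, name, expected):
        counts = dx.REFERENCE_CONTINGENCY_TABLES[name]["counts"]
        res = dx.pearson_chi_square(counts)
        assert res.statistic == pytest.approx(expected, abs=5e-4)

    def test_identical_proportions_zero(self):
        assert dx.pearson_chi_square([[10, 20], [10, 20]]).statistic == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        t = rng.integers(1, 40, size=(3, 2)).astype(float)
        obs = t
        exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
        chi2_direct = ((obs - exp) ** 2 / exp).sum()
        assert dx.pearson_chi_square(t).statistic == pytest.approx(
            chi2_direct, abs=1e-10)

    def test_equals_squared_two_proportion_z(self, rng):
        t = rng.integers(5, 30, size=(2, 2)).astype(float)
        chi2 = dx.pearson_chi_square(t).statistic
        n1, n2 = t[0].sum(), t[1].sum()
        p1, p2 = t[0, 0] / n1, t[1, 0] / n2
        p = (t[0, 0] + t[1, 0]) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z ** 2, rel=1e-10)

    def test_relabeling_invariance(self):
        t = np.array([[11, 12], [33, 16]])
        assert dx.pearson_chi_square(t).statistic == pytest.approx(
            dx.pearson_chi_square(t[:, ::-1]).statistic, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dx.pearson_chi_square([[0, 5], [0, 7]])


def _fisher_enumeration(table):
    """Two-sided Fisher p: sum hypergeometric probabilities <= P(observed)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestFisher:
    def test_diagonal_two_by_two(self):
        assert dx.fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        assert dx.fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        t = r.integers(0, 12, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        assert dx.fisher_exact(t).p_value == pytest.approx(
            _fisher_enumeration(t), abs=1e-12)


class TestTwoSampleT:
    def test_identical_samples_zero(self):
        res = dx.two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pooled_value(self):
        res = dx.two_sample_t([1.0, 2, 3], [2.0, 3, 4], variance_rule="pooled")
        # sp = 1, SE = sqrt(2/3), t = -1/sqrt(2/3)
        assert res.statistic == pytest.approx(-1.2247, abs=5e-5)

    def test_welch_triggered_by_unequal_variance(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 10, 200)
        res = dx.two_sample_t(x, y)
        assert res.name == "welch_t"
        assert res.extra["levene_p"] < 0.1

    def test_zero_variance_equal_means(self):
        res = dx.two_sample_t([2.0, 2, 2], [2.0, 2, 2])
        assert res.statistic == 0.0


class TestMannWhitney:
    def test_complete_separation(self):
        res = dx.mann_whitney_u([1.0, 2], [3.0, 4])
        assert res.statistic == 0.0

    def test_identical_multisets_zero_z(self):
        res = dx.mann_whitney_u([1.0, 2, 3], [3.0, 1, 2])
        assert abs(res.extra["z"]) < 1e-12

    def test_small_sample_p_close_to_exact_permutation(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact").pvalue
        assert dx.mann_whitney_u(x, y).p_value == pytest.approx(exact, abs=0.01)


class TestKappa:
    def test_identical_ratings(self):
        a = ["x", "y", "x", "z"] * 5
        res = dx.cohens_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)
        assert res.percent_agreement == pytest.approx(100.0)

    def test_hand_computed_confusion(self):
        # confusion [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5 -> kappa 0.4
        a = ["p"] * 25 + ["n"] * 25
        b = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
        res = dx.cohens_kappa(a, b)
        assert res.kappa == pytest.approx(0.4, abs=1e-12)
        assert res.ci95[0] < 0.4 < res.ci95[1]

    def test_independent_ratings_near_zero(self, rng):
        a = rng.integers(0, 3, 10_000)
        b = rng.integers(0, 3, 10_000)
        assert abs(dx.cohens_kappa(a, b).kappa) < 0.05

    def test_single_shared_category_flagged(self):
        res = dx.cohens_kappa(["a"] * 10, ["a"] * 10)
        assert np.isnan(res.kappa)
        assert "kappa_undefined_single_category" in res.flags

    def test_relabeling_invariance(self, rng):
        a = rng.integers(0, 3, 500)
        b = rng.integers(0, 3, 500)
        relabel = {0: "u", 1: "v", 2: "w"}
        k1 = dx.cohens_kappa(a, b).kappa
        k2 = dx.cohens_kappa([relabel[v] for v in a],
                             [relabel[v] for v in b]).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)


class TestLogistic:
    def test_null_predictor_odds_ratio_one(self, rng):
        x = rng.normal(size=400)
        y = np.tile([0, 1], 200)
        model = dx.logistic_fit(pd.DataFrame({"x": x}), y)
        assert model.params.loc["x", "or"] == pytest.approx(1.0, abs=0.3)
        assert not model.separation

    def test_univariate_or_equals_cross_product_ratio(self):
        # binary predictor from the reference microcalcification counts
        y = np.array([1] * 23 + [0] * 49)
        x = np.array([1] * 15 + [0] * 8 + [1] * 16 + [0] * 33)
        model = dx.logistic_fit(pd.DataFrame({"x": x}), y)
        assert model.params.loc["x", "or"] == pytest.approx(
            (15 * 33) / (8 * 16), rel=1e-4)

    def test_coefficient_recovery_within_2se(self, rng):
        n = 5000
        beta = np.array([0.5, -0.8, 0.3])
        X = rng.normal(size=(n, 3))
        logit = -0.5 + X @ beta
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        model = dx.logistic_fit(pd.DataFrame(X, columns=list("abc")), y)
        for name, true in zip("abc", beta):
            est = model.params.loc[name, "beta"]
            se = model.params.loc[name, "se"]
            assert abs(est - true) < 2 * se

    def test_complete_separation_reported(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.astype(int)
        model = dx.logistic_fit(pd.DataFrame({"x": x}), y)
        assert model.separation


class TestROC:
    def test_separable_auc_one(self):
        r = dx.roc_analysis([3.0, 4, 1, 2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(1.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_interleaved_auc_quarter(self):
        r = dx.roc_analysis([1.0, 3, 2, 4], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.25)

    def test_auc_equals_mann_whitney_identity(self, rng):
        scores = rng.normal(size=120)
        labels = rng.integers(0, 2, 120)
        if labels.sum() in (0, 120):
            labels[0] = 1 - labels[0]
        n1, n0 = labels.sum(), (1 - labels).sum()
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
        assert dx.roc_analysis(scores, labels).auc == pytest.approx(
            u / (n1 * n0), abs=1e-12)

    def test_auc_antisymmetry(self, rng):
        scores = rng.normal(size=80)
        labels = np.tile([0, 1], 40)
        a1 = dx.roc_analysis(scores, labels).auc
        a2 = dx.roc_analysis(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=100)
        labels = np.tile([0, 1], 50)
        assert dx.roc_analysis(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_constant_scores_degenerate(self):
        r = dx.roc_analysis(np.ones(10), np.tile([0, 1], 5))
        assert r.auc == pytest.approx(0.5)
        assert r.degenerate


class TestCombineModalities:
    def test_perfect_feature_gives_auc_one(self, rng):
        y = np.tile([0, 1], 50)
        df = pd.DataFrame({
            "her2": np.where(y == 1, "positive", "negative"),
            "perfect": y * 10.0 + rng.normal(0, 0.1, 100),
            "noise": rng.normal(size=100),
        })
        out = dx.combine_modalities(df, {"A": ["perfect"], "B": ["noise"]})
        assert out["A"].auc == pytest.approx(1.0)
        assert set(out) == {"A", "B", "A+B"}

    def test_nested_informative_features_nondecreasing_auc(self, rng):
        n = 300
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({
            "her2": np.where(y == 1, "positive", "negative"),
            "s1": y + rng.normal(0, 1.5, n),
            "s2": y + rng.normal(0, 1.5, n),
        })
        out = dx.combine_modalities(df, {"A": ["s1"], "B": ["s2"]})
        assert out["A+B"].auc >= max(out["A"].auc, out["B"].auc) - 1e-9

    def test_null_features_auc_near_half(self):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.tile([0, 1], 100)
            df = pd.DataFrame({
                "her2": np.where(y == 1, "positive", "negative"),
                "n1": r.normal(size=200), "n2": r.normal(size=200),
            })
            out = dx.combine_modalities(df, {"A": ["n1", "n2"]})
            aucs.append(out["A"].auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestCohortReport:
    def test_group_comparison_schema_and_direction(self):
        df = phantom.simulate_cohort(phantom.default_cohort_spec(
            n_pos=400, n_neg=400, seed=2))
        rep = dx.group_comparison_table(df)
        assert set(rep.columns) >= {"feature", "test", "statistic", "p_value"}
        row = rep[rep.feature == "max_diameter_cm"].iloc[0]
        assert row.p_value < 0.05  # large-n cohort resolves the true difference
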