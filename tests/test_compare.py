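"""Univariate group-comparison tests and proportional-odds regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from icftraj import compare
from icftraj.compare import (
    TestKind,
    anova_f,
    choose_categorical_test,
    enumerated_total_mass,
    fisher_exact_rxc,
    kruskal_wallis,
    or_ci,
    ordinal_logit_fit,
    pearson_chi2,
    univariate_table,
)

Z975 = stats.norm.ppf(0.975)


def simulate_proportional_odds(n, rng, beta_age=0.08, beta_bin=1.5,
                               thresholds=(3.0, 5.5, 7.5)):
    age = rng.normal(55, 15, n)
    flag = rng.random(n) < 0.25
    eta = beta_age * age + beta_bin * flag
    cum = expit(np.asarray(thresholds)[None, :] - eta[:, None])
    y = (rng.uniform(size=n)[:, None] > cum).sum(axis=1) + 1
    return pd.DataFrame(
        {"group": y, "age": age, "dysphagia": np.where(flag, "yes", "no")}
    )


class TestPearsonChi2:
    def test_matches_brute_force_oracle_on_random_tables(self):
        """Sum over cells of (O-E)^2/E with margin-product expecteds."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            r, c = rng.integers(2, 5, size=2)
            t = rng.integers(1, 30, size=(r, c))
            res = pearson_chi2(t)
            total = t.sum()
            exp = np.outer(t.sum(1), t.sum(0)) / total
            oracle = ((t - exp) ** 2 / exp).sum()
            assert res.statistic == pytest.approx(oracle)
            assert res.df == (r - 1) * (c - 1)
            assert res.p_value == pytest.approx(stats.chi2.sf(oracle, res.df))

    def test_identical_row_proportions_give_zero(self):
        res = pearson_chi2([[10, 20, 30], [5, 10, 15]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_dropped_with_note(self):
        res = pearson_chi2([[5, 0, 7], [3, 0, 9]], "x")
        assert res.notes
        assert res.statistic == pytest.approx(
            pearson_chi2([[5, 7], [3, 9]]).statistic
        )

    def test_invalid_table_raises(self):
        with pytest.raises(ValueError):
            pearson_chi2([[1, -2], [3, 4]])


class TestFisherExact:
    def test_2x2_matches_independent_enumeration_oracle(self):
        # R fisher.test(matrix(c(1,9,11,3), nrow=2, byrow=TRUE)) -> 0.00275946
        res = fisher_exact_rxc([[1, 9], [11, 3]])
        assert res.p_value == pytest.approx(0.0027594561852, abs=1e-9)
        # scipy's two-sided 2x2 exact test agrees
        assert res.p_value == pytest.approx(
            stats.fisher_exact([[1, 9], [11, 3]])[1], abs=1e-12
        )

    def test_4x2_matches_r_oracle(self):
        # R fisher.test on the 4-group dysphagia table -> 0.007379356
        res = fisher_exact_rxc([[1, 4, 9, 8], [16, 30, 17, 10]])
        assert res.p_value == pytest.approx(0.007379356, abs=1e-8)

    def test_probabilities_of_all_tables_sum_to_one(self):
        for t in ([[1, 4, 9, 8], [16, 30, 17, 10]], [[2, 3], [4, 1]], [[1, 2, 3], [4, 5, 6]]):
            assert enumerated_total_mass(t) == pytest.approx(1.0, abs=1e-10)

    def test_zero_row_removal_leaves_p_unchanged(self):
        full = fisher_exact_rxc([[2, 7], [0, 0], [8, 1]], "v")
        reduced = fisher_exact_rxc([[2, 7], [8, 1]])
        assert full.p_value == pytest.approx(reduced.p_value)

    def test_monte_carlo_within_three_se_of_enumeration(self):
        table = [[1, 4, 9, 8], [16, 30, 17, 10]]
        exact = fisher_exact_rxc(table).p_value
        mc = fisher_exact_rxc(table, mode="monte_carlo", seed=0, n_draws=100_000)
        assert abs(mc.p_value - exact) <= 3 * mc.mc_se

    def test_budget_exceeded_instructs_fallback(self):
        with pytest.raises(compare.EnumerationBudgetError, match="monte_carlo"):
            fisher_exact_rxc(
                np.full((4, 4), 30), mode="enumerate", max_tables=1000
            )


class TestContinuousTests:
    def test_identical_group_means_give_zero_f(self):
        res = anova_f([[1.0, 3.0], [2.0, 2.0], [0.0, 4.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_zero_within_variance_flagged(self):
        res = anova_f([[0.0, 0.0], [1.0, 1.0]])
        assert np.isinf(res.statistic)
        assert res.notes

    def test_three_group_textbook_arithmetic(self):
        # groups (1,2),(2,3),(4,6): SSB=13, SSW=3 -> F = 6.5/1 = 6.5, df (2,3)
        res = anova_f([[1, 2], [2, 3], [4, 6]])
        assert res.statistic == pytest.approx(6.5)
        assert res.df == 2
        assert res.p_value == pytest.approx(stats.f.sf(6.5, 2, 3))

    def test_kruskal_all_identical_values(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_kruskal_hand_ranked_no_ties(self):
        # groups (1,2),(3,4): ranks (1,2),(3,4); H = 12/20 * (2+2) = 2.4
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.statistic == pytest.approx(2.4)

    def test_kruskal_ties_match_midrank_formula(self):
        groups = [[1, 2, 2, 3], [2, 3, 3, 4], [1, 1, 4, 4]]
        pooled = np.concatenate([np.asarray(g, float) for g in groups])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        splits = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
        h = 12 / (n * (n + 1)) * sum(
            len(r) * (r.mean() - (n + 1) / 2) ** 2 for r in splits
        )
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - (counts**3 - counts).sum() / (n**3 - n)
        assert kruskal_wallis(groups).statistic == pytest.approx(h)


class TestOrCi:
    def test_null_effect(self):
        o, lo, hi = or_ci(0.0, 1.0)
        assert o == 1.0
        assert lo == pytest.approx(np.exp(-Z975))
        assert hi == pytest.approx(np.exp(Z975))

    @pytest.mark.parametrize(
        "beta,expected_or", [(0.109, 1.12), (2.159, 8.66), (3.180, 24.05)]
    )
    def test_reference_point_estimates(self, beta, expected_or):
        assert round(or_ci(beta, 1.0)[0], 2) == expected_or

    def test_interval_contains_point_estimate(self):
        o, lo, hi = or_ci(0.7, 0.3)
        assert lo < o < hi

    def test_bad_se_raises(self):
        with pytest.raises(ValueError):
            or_ci(1.0, 0.0)


class TestOrdinalLogit:
    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(5)
        df = simulate_proportional_odds(3000, rng)
        fit = ordinal_logit_fit(df, ["age", "dysphagia"])
        terms = {t.name: t for t in fit.terms}
        assert terms["age"].beta == pytest.approx(0.08, abs=3 * terms["age"].se)
        assert terms["dysphagia[yes]"].beta == pytest.approx(
            1.5, abs=3 * terms["dysphagia[yes]"].se
        )
        assert (np.diff(fit.thresholds) > 0).all()
        assert fit.lr_chi2 > 0 and fit.lr_p < 1e-6

    def test_wald_or_and_ci_consistent_with_estimates(self):
        rng = np.random.default_rng(6)
        fit = ordinal_logit_fit(simulate_proportional_odds(1500, rng), ["age"])
        t = fit.terms[0]
        assert t.wald_chi2 == pytest.approx((t.beta / t.se) ** 2)
        assert t.odds_ratio == pytest.approx(np.exp(t.beta))
        assert t.ci_low == pytest.approx(np.exp(t.beta - Z975 * t.se), rel=1e-6)
        assert t.ci_high == pytest.approx(np.exp(t.beta + Z975 * t.se), rel=1e-6)

    def test_binary_collapse_matches_logistic_regression(self):
        """Dichotomising the ordinal outcome at a cutpoint and fitting a
        logistic regression recovers the same slope (proportional odds)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        df = simulate_proportional_odds(4000, rng)
        fit = ordinal_logit_fit(df, ["age", "dysphagia"], diagnostics=False)
        po_beta = {t.name: t.beta for t in fit.terms}
        X = sm.add_constant(
            pd.DataFrame(
                {"age": df["age"], "dysphagia[yes]": (df["dysphagia"] == "yes") * 1.0}
            )
        )
        for cut in (1, 2, 3):
            logit = sm.Logit((df["group"] > cut).astype(float), X).fit(disp=0)
            for name in ("age", "dysphagia[yes]"):
                assert logit.params[name] == pytest.approx(
                    po_beta[name], abs=3.5 * logit.bse[name]
                )

    def test_parallel_lines_not_rejected_on_po_data(self):
        rng = np.random.default_rng(8)
        fit = ordinal_logit_fit(simulate_proportional_odds(2000, rng), ["age"])
        assert fit.parallel_df == 2  # (J-2) * p with J=4, p=1
        assert fit.parallel_chi2 >= 0
        assert fit.parallel_p > 0.01

    def test_positive_beta_raises_severe_probability(self):
        rng = np.random.default_rng(9)
        df = simulate_proportional_odds(2000, rng)
        fit = ordinal_logit_fit(df, ["age", "dysphagia"], diagnostics=False)
        betas = np.array([t.beta for t in fit.terms])
        x_low = np.array([40.0, 0.0])
        for bump in ([10.0, 0.0], [0.0, 1.0]):
            p0 = compare.predicted_severe_probability(betas, fit.thresholds, x_low)
            p1 = compare.predicted_severe_probability(
                betas, fit.thresholds, x_low + np.array(bump)
            )
            assert p1 > p0

    def test_quasi_separation_capped_and_flagged(self):
        n = 120
        g = np.repeat([1, 2, 3, 4], n // 4)
        flag = np.where(g >= 3, "yes", "no")  # perfectly separating predictor
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"group": g, "flag": flag, "age": rng.normal(55, 10, n)})
        fit = ordinal_logit_fit(df, ["flag", "age"], diagnostics=False)
        term = {t.name: t for t in fit.terms}["flag[yes]"]
        assert term.capped
        assert abs(term.beta) <= 15.0
        assert any("separation" in w for w in fit.warnings)

    def test_constant_predictor_raises(self):
        df = pd.DataFrame({"group": [1, 2, 3, 4] * 5, "x": 1.0})
        with pytest.raises(ValueError, match="constant"):
            ordinal_logit_fit(df, ["x"])

    def test_binary_outcome_rejected(self):
        df = pd.DataFrame({"group": [1, 2] * 10, "x": np.arange(20.0)})
        with pytest.raises(ValueError, match="3 ordinal"):
            ordinal_logit_fit(df, ["x"])


class TestUnivariateTable:
    def test_dispatch_and_shape(self):
        rng = np.random.default_rng(11)
        n = 200
        df = pd.DataFrame(
            {
                "group": rng.integers(1, 5, n),
                "age": rng.normal(60, 12, n),
                "disease_course": rng.lognormal(4, 0.8, n),
                "dysphagia": np.where(rng.random(n) < 0.2, "yes", "no"),
            }
        )
        tab = univariate_table(
            df, continuous=["age"], nonnormal=["disease_course"],
            categorical=["dysphagia"],
        )
        assert list(tab["variable"]) == ["age", "disease_course", "dysphagia"]
        assert tab["p_value"].between(0, 1).all()
        assert tab.loc[0, "test"] == "anova_f"
        assert tab.loc[1, "test"] == "kruskal_wallis"

    def test_sparse_table_triggers_exact_test(self):
        sparse = [[1, 0, 2, 1], [30, 40, 28, 30]]
        assert choose_categorical_test(sparse) is TestKind.FISHER_EXACT
        filled = [[20, 25, 22, 21], [30, 40, 28, 30]]
        assert choose_categorical_test(filled) is TestKind.PEARSON_CHI2
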