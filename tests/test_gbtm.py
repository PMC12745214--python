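"""Censored-normal mixture: kernel, likelihood, EM fit and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from icftraj import gbtm, items, simulate
from icftraj.gbtm import (
    TrajectorySpec,
    avepp,
    bic,
    cnorm_logdensity,
    fit,
    mixture_loglikelihood,
    select_model,
)


def patients_frame(totals_by_patient, day_step=14):
    rows = []
    for pid, totals in totals_by_patient.items():
        for j, y in enumerate(totals):
            rows.append({"patient_id": pid, "day": j * day_step, "total": y})
    return pd.DataFrame(rows)


class TestCnormKernel:
    def test_interior_mode_standard_normal(self):
        assert cnorm_logdensity(5.0, 5.0, 1.0, (0, 200)) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_lower_bound_at_mean_is_log_half(self):
        assert cnorm_logdensity(0.0, 0.0, 3.0, (0, 200)) == pytest.approx(np.log(0.5))

    def test_upper_bound_mass(self):
        expected = np.log(stats.norm.sf(1.0))
        assert cnorm_logdensity(200.0, 190.0, 10.0, (0, 200)) == pytest.approx(expected)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            cnorm_logdensity(-1.0, 0.0, 1.0, (0, 200))

    @pytest.mark.parametrize("mu,sigma", [(100.0, 10.0), (5.0, 20.0), (195.0, 30.0)])
    def test_total_mass_is_one(self, mu, sigma):
        """Interior density integral plus the two boundary masses sum to 1."""
        interior, _ = integrate.quad(
            lambda y: np.exp(cnorm_logdensity(y, mu, sigma, (0, 200))), 1e-9, 200 - 1e-9,
            limit=200,
        )
        mass = (
            interior
            + np.exp(cnorm_logdensity(0.0, mu, sigma, (0, 200)))
            + np.exp(cnorm_logdensity(200.0, mu, sigma, (0, 200)))
        )
        assert mass == pytest.approx(1.0, abs=1e-7)


class TestMixtureLoglik:
    def test_single_group_reduces_to_normal_sum(self):
        df = patients_frame({"a": [50, 48], "b": [60, 55, 52]})
        spec = TrajectorySpec(1, 0, bounds=(-np.inf, np.inf))
        ll = mixture_loglikelihood(df, spec, [1.0], [np.array([55.0])], 6.0)
        direct = stats.norm.logpdf(df["total"], 55.0, 6.0).sum()
        assert ll == pytest.approx(direct)

    def test_duplicating_patients_doubles_loglik(self):
        df = patients_frame({"a": [50, 48], "b": [120, 110]})
        df2 = pd.concat(
            [df, df.assign(patient_id=df["patient_id"] + "_copy")], ignore_index=True
        )
        spec = TrajectorySpec(2, 0)
        args = ([0.4, 0.6], [np.array([50.0]), np.array([115.0])], 8.0)
        assert mixture_loglikelihood(df2, spec, *args) == pytest.approx(
            2 * mixture_loglikelihood(df, spec, *args)
        )

    def test_two_by_two_hand_computed(self):
        """2 patients x 2 groups x 1 time point vs explicit mixture sums."""
        df = patients_frame({"a": [40], "b": [90]})
        spec = TrajectorySpec(2, 0, bounds=(0, 200))
        p = [0.3, 0.7]
        mus, sigma = [50.0, 100.0], 15.0
        expected = sum(
            np.log(
                p[0] * stats.norm.pdf(y, mus[0], sigma)
                + p[1] * stats.norm.pdf(y, mus[1], sigma)
            )
            for y in (40.0, 90.0)
        )
        ll = mixture_loglikelihood(df, spec, p, [np.array([m]) for m in mus], sigma)
        assert ll == pytest.approx(expected)

    def test_non_finite_parameter_raises(self):
        df = patients_frame({"a": [40]})
        with pytest.raises(ValueError):
            mixture_loglikelihood(
                df, TrajectorySpec(1, 0), [np.nan], [np.array([50.0])], 5.0
            )


@pytest.fixture(scope="module")
def cohort_totals_1000():
    cfg = simulate.default_stroke_config(n_patients=1000, seed=3)
    return items.totals_frame(simulate.generate(cfg).assessments)


class TestFit:
    def test_noise_free_single_group_recovers_exactly(self):
        true = np.array([5.0, -30.0, 80.0])  # quadratic in day/100
        days = np.arange(0, 71, 14)
        df = pd.DataFrame(
            [
                {"patient_id": f"p{i:02d}", "day": d, "total": np.polyval(true, d / 100)}
                for i in range(25)
                for d in days
            ]
        )
        m = fit(df, TrajectorySpec(1, 2, bounds=(0.0, 200.0)), n_starts=1)
        assert np.abs(m.coeffs[0] - true).max() < 1e-6

    def test_uncensored_single_group_matches_ols(self):
        rng = np.random.default_rng(4)
        true = np.array([-20.0, 70.0])
        days = np.arange(0, 57, 14)
        df = pd.DataFrame(
            [
                {
                    "patient_id": f"p{i:02d}",
                    "day": d,
                    "total": np.polyval(true, d / 100) + rng.normal(0, 7),
                }
                for i in range(40)
                for d in days
            ]
        )
        m = fit(df, TrajectorySpec(1, 1, bounds=(-np.inf, np.inf)), n_starts=1)
        X = np.vander(df["day"].to_numpy() / 100, 2)
        ols, *_ = np.linalg.lstsq(X, df["total"].to_numpy(), rcond=None)
        assert np.abs(m.coeffs[0] - ols).max() < 1e-6

    def test_em_loglik_monotone(self, cohort_totals_1000):
        m = fit(cohort_totals_1000, TrajectorySpec(4), n_starts=1, seed=0)
        diffs = np.diff(m.loglik_history)
        assert (diffs >= -1e-7 * np.abs(m.loglik)).all()

    def test_patient_order_permutation_invariance(self, cohort_totals_1000):
        df = cohort_totals_1000
        rng = np.random.default_rng(0)
        pids = df["patient_id"].unique()
        shuffled = pd.concat(
            [df[df["patient_id"] == p] for p in rng.permutation(pids)],
            ignore_index=True,
        )
        m1 = fit(df, TrajectorySpec(4), n_starts=1, seed=0)
        m2 = fit(shuffled, TrajectorySpec(4), n_starts=1, seed=0)
        assert m1.loglik == pytest.approx(m2.loglik, rel=1e-6)
        assert m1.bic == pytest.approx(m2.bic, rel=1e-6)
        for b1, b2 in zip(m1.coeffs, m2.coeffs):
            assert b1 == pytest.approx(b2, rel=1e-4, abs=1e-4)

    def test_groups_labelled_by_ascending_severity(self, cohort_totals_1000):
        m = fit(cohort_totals_1000, TrajectorySpec(4), n_starts=1, seed=0)
        day0 = m.day0_means()
        assert (np.diff(day0) > 0).all()

    def test_posterior_rows_and_probs_normalised(self, cohort_totals_1000):
        m = fit(cohort_totals_1000, TrajectorySpec(3), n_starts=1, seed=0)
        assert m.posteriors.sum(axis=1) == pytest.approx(np.ones(m.n_subjects))
        assert m.group_probs.sum() == pytest.approx(1.0)
        assert m.shares.sum() == pytest.approx(1.0)

    def test_too_few_patients_raises(self):
        df = patients_frame({"a": [10, 20]})
        with pytest.raises(ValueError, match="patients"):
            fit(df, TrajectorySpec(2))


class TestBic:
    def test_zero_loglik_is_pure_penalty(self):
        assert bic(0.0, 3, 100) == pytest.approx(-1.5 * np.log(100))

    def test_direct_arithmetic(self):
        assert bic(-100.0, 5, 95) == pytest.approx(-100 - 2.5 * np.log(95))

    def test_no_params_no_penalty(self):
        assert bic(-42.0, 0, 10) == -42.0

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)


class TestAvepp:
    def test_one_hot_posteriors_give_one(self):
        post = np.eye(3)[[0, 1, 2, 0]]
        assign = post.argmax(axis=1)
        assert avepp(post, assign) == pytest.approx(np.ones(3))

    def test_maximal_ambiguity_ties_to_lower_index(self):
        post = np.full((4, 2), 0.5)
        assign = post.argmax(axis=1)
        assert (assign == 0).all()
        out = avepp(post, assign)
        assert out[0] == pytest.approx(0.5)
        assert np.isnan(out[1])  # empty group -> undefined marker

    def test_hand_written_rows(self):
        post = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8]])
        assign = post.argmax(axis=1)
        out = avepp(post, assign)
        assert out[0] == pytest.approx((0.9 + 0.6) / 2)
        assert out[1] == pytest.approx(0.8)


class TestSelection:
    def test_four_group_cohort_selects_four_over_three(self, cohort_totals_1000):
        sel = select_model(cohort_totals_1000, K_range=[3, 4], n_starts=1, seed=0)
        assert sel.chosen.spec.n_groups == 4
        assert sel.admissible
        # chosen is the admissible candidate with BIC closest to zero
        adm = [c for c in sel.candidates if c.admissible]
        assert sel.chosen.bic == pytest.approx(max(c.bic for c in adm))

    def test_single_inadmissible_candidate_flagged(self):
        # two clearly separated groups, forced into a 1-group model menu is
        # admissible by construction; force a share violation with K too large
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            base = 40.0 if i % 2 else 150.0
            for d in (0, 14, 28):
                rows.append(
                    {"patient_id": f"p{i:02d}", "day": d,
                     "total": base + rng.normal(0, 3)}
                )
        df = pd.DataFrame(rows)
        with pytest.warns(UserWarning, match="admissible"):
            sel = select_model(df, K_range=[5], order_menu=0, n_starts=1, seed=0)
        assert not sel.admissible
        assert not sel.candidates[0].admissible

    def test_empty_k_range_raises(self, cohort_totals_1000):
        with pytest.raises(ValueError):
            select_model(cohort_totals_1000, K_range=[])
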