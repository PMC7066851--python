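import numpy as np
import pandas as pd
import pytest

from m6apattern import (
    SimulationParams,
    cox_fit,
    cox_screen,
    encode_covariates,
    km_estimate,
    logrank_test,
    max_stat_cutpoint,
    simulate_cohort,
    survival_at,
)

from oracles import (
    cox_grid_beta,
    km_survival_empirical,
    logrank_z_two_group,
)


class TestKaplanMeier:
    def test_hand_fixture(self):
        curve = km_estimate([5, 10], [1, 0])
        assert curve.survival_at(5) == pytest.approx(0.5)
        assert curve.survival_at(10) == pytest.approx(0.5)
        assert survival_at(curve, 4.9) == 1.0

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([3, 7, 9], [0, 0, 0])
        assert curve.survival_at(100) == 1.0

    def test_monotone_right_continuous(self, rng):
        t = rng.exponential(50, 200)
        e = rng.integers(0, 2, 200)
        e[0] = 1
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival_at(0) == 1.0

    def test_equals_empirical_without_censoring(self, rng):
        t = rng.exponential(30, 500)
        curve = km_estimate(t, np.ones(500, dtype=int))
        for q in [5.0, 20.0, 60.0]:
            assert curve.survival_at(q) == pytest.approx(
                km_survival_empirical(t, q)
            )

    def test_exponential_closed_form(self, rng):
        lam = 0.01
        t = rng.exponential(1 / lam, 2000)
        curve = km_estimate(t, np.ones(2000, dtype=int))
        expected = np.exp(-lam * 60)
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(curve.survival_at(60) - expected) <= 3 * se

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(40, 150)
        e = rng.integers(0, 2, 150)
        e[:3] = 1
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in [10.0, 30.0, 80.0]:
            assert curve.survival_at(q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10
            )


class TestLogrank:
    def test_identical_groups_null(self):
        t = [3.0, 5.0, 8.0, 3.0, 5.0, 8.0]
        e = [1, 0, 1, 1, 0, 1]
        res = logrank_test(t, e, ["a", "a", "a", "b", "b", "b"])
        assert res.chisq == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_fixture(self):
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["g1", "g1", "g2", "g2"])
        assert res.o_minus_e[0] == pytest.approx(1.1667, abs=1e-4)
        assert res.variance[0, 0] == pytest.approx(0.4722, abs=1e-4)
        assert res.chisq == pytest.approx(2.882, abs=1e-3)

    def test_relabeling_invariance(self, rng):
        t = rng.exponential(30, 80)
        e = rng.integers(0, 2, 80)
        e[:2] = 1
        g = rng.choice(["x", "y"], 80)
        res1 = logrank_test(t, e, g)
        res2 = logrank_test(t, e, np.where(g == "x", "y", "x"))
        assert res1.chisq == pytest.approx(res2.chisq)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_matches_lifelines_three_groups(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(30, 120)
        e = rng.integers(0, 2, 120)
        e[:3] = 1
        g = rng.choice(["a", "b", "c"], 120)
        mine = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.chisq == pytest.approx(ref.test_statistic, rel=1e-8)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-8)


class TestCoxFit:
    def test_hand_fixture_vs_grid_oracle(self):
        fit = cox_fit([1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0])
        oracle = cox_grid_beta([1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0])
        assert fit.beta[0] == pytest.approx(oracle, abs=2e-3)
        assert fit.beta[0] == pytest.approx(0.940, abs=2e-3)
        assert fit.hr[0] == pytest.approx(2.56, abs=0.01)
        assert fit.converged

    def test_translation_invariance(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        f1 = cox_fit([1, 2, 3, 4], [1, 1, 1, 1], x)
        f2 = cox_fit([1, 2, 3, 4], [1, 1, 1, 1], x + 5.0)
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-9)

    def test_loglik_improves_over_null(self, rng):
        t = rng.exponential(30, 100)
        e = np.ones(100, dtype=int)
        x = rng.normal(size=100)
        fit = cox_fit(t, e, x)
        assert fit.loglik >= fit.loglik_null - 1e-12

    def test_ci_brackets_hr(self, rng):
        fit = cox_fit(
            rng.exponential(30, 60), np.ones(60, dtype=int), rng.normal(size=60)
        )
        assert fit.ci_lower[0] <= fit.hr[0] <= fit.ci_upper[0]

    def test_zero_variance_covariate_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            cox_fit([1, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0])

    def test_separation_flagged_and_capped(self):
        # perfectly separated: low x dies late, high x dies early
        t = [1, 2, 3, 10, 11, 12]
        e = [1, 1, 1, 1, 1, 1]
        x = [1, 1, 1, 0, 0, 0]
        fit = cox_fit(t, e, x)
        assert not fit.converged
        assert abs(fit.beta[0]) <= 20.0

    def test_matches_lifelines_multivariable(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1 / (0.02 * np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        c = rng.uniform(0, 80, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        fit = cox_fit(time, event, X, names=["x0", "x1"])
        df = pd.DataFrame({"t": time, "e": event, "x0": X[:, 0], "x1": X[:, 1]})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # continuous times: no ties, so Breslow and Efron coincide
        np.testing.assert_allclose(
            fit.beta, ref.params_[["x0", "x1"]].to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(
            fit.se, ref.standard_errors_[["x0", "x1"]].to_numpy(), atol=1e-5
        )

    def test_parameter_recovery_simulation(self):
        """True beta = log 2 under exponential baseline: small bias and
        near-nominal CI coverage."""
        rng = np.random.default_rng(77)
        betas, covered = [], 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=500)
            t_event = rng.exponential(1 / (0.01 * np.exp(0.693 * x)))
            c = rng.uniform(0, 120, 500)
            time = np.minimum(t_event, c)
            event = (t_event <= c).astype(int)
            fit = cox_fit(time, event, x)
            betas.append(fit.beta[0])
            lo = fit.beta[0] - 1.96 * fit.se[0]
            hi = fit.beta[0] + 1.96 * fit.se[0]
            covered += lo <= 0.693 <= hi
        assert abs(np.mean(betas) - 0.693) <= 0.05
        assert 0.92 <= covered / reps <= 0.98


class TestEncodeCovariates:
    def test_one_hot_reference_is_lexicographic_first(self):
        clin = pd.DataFrame(
            {"stage": ["II", "I", "III", "I"], "age": [60.0, 50.0, 70.0, 55.0]},
            index=list("abcd"),
        )
        X = encode_covariates(clin, ["age", "stage"])
        assert list(X.columns) == ["age", "stage[II]", "stage[III]"]
        assert X.loc["b", ["stage[II]", "stage[III]"]].tolist() == [0.0, 0.0]


class TestCoxScreen:
    def test_latent_aligned_gene_kept(self, cohort):
        expr = cohort.expression.copy()
        latent = cohort.truth.latent_score
        expr.loc["HAZARD_GENE"] = latent + np.random.default_rng(0).normal(
            0, 0.1, len(latent)
        )
        table = cox_screen(expr, cohort.clinical, ["HAZARD_GENE"])
        assert table.loc["HAZARD_GENE", "keep"]
        assert table.loc["HAZARD_GENE", "beta"] > 0

    def test_zero_variance_flagged_not_kept(self, small_cohort):
        expr = small_cohort.expression.copy()
        expr.loc["FLAT"] = 3.0
        table = cox_screen(expr, small_cohort.clinical, ["FLAT"])
        assert not table.loc["FLAT", "keep"]
        assert not table.loc["FLAT", "converged"]

    def test_noise_gene_type_one_error(self):
        rng = np.random.default_rng(123)
        kept = 0
        reps = 200
        c = simulate_cohort(
            SimulationParams(seed=0, n_samples=150, n_deg=1, n_background=1,
                             n_cell_types=1, markers_per_cell_type=1)
        )
        for _ in range(reps):
            expr = c.expression.iloc[:1].copy()
            expr.loc["NOISE"] = rng.normal(size=150)
            table = cox_screen(expr, c.clinical, ["NOISE"], alpha=0.05)
            kept += int(table.loc["NOISE", "keep"])
        rate = kept / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se


class TestMaxStatCutpoint:
    def test_fixture_matches_enumeration_oracle(self):
        score = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([10.0, 9.0, 2.0, 1.0])
        events = np.ones(4, dtype=int)
        res = max_stat_cutpoint(score, times, events, minprop=0.25)
        oracle = {
            c: logrank_z_two_group(times, events, score <= c)
            for c in [1.0, 2.0, 3.0]
        }
        np.testing.assert_allclose(
            res.statistics, [oracle[c] for c in [1.0, 2.0, 3.0]], atol=1e-12
        )
        best = max(oracle, key=lambda c: abs(oracle[c]))
        assert res.cutpoint == best == 3.0
        assert res.max_stat == pytest.approx(np.sqrt(3.0), abs=1e-10)

    def test_random_fixture_matches_oracle(self, rng):
        score = rng.normal(size=40)
        t = rng.exponential(30, 40)
        e = rng.integers(0, 2, 40)
        e[:2] = 1
        res = max_stat_cutpoint(score, t, e, minprop=0.2)
        for c, z in zip(res.candidates, res.statistics):
            assert z == pytest.approx(
                logrank_z_two_group(t, e, score <= c), abs=1e-10
            )

    def test_monotone_transform_invariance(self, rng):
        score = rng.normal(size=60)
        t = rng.exponential(30, 60)
        e = np.ones(60, dtype=int)
        r1 = max_stat_cutpoint(score, t, e)
        r2 = max_stat_cutpoint(np.exp(score), t, e)
        assert r2.cutpoint == pytest.approx(np.exp(r1.cutpoint))
        assert r1.max_stat == pytest.approx(r2.max_stat)
        assert (r1.n_low, r1.n_high) == (r2.n_low, r2.n_high)

    def test_group_size_constraint(self, rng):
        score = rng.normal(size=50)
        t = rng.exponential(30, 50)
        e = np.ones(50, dtype=int)
        res = max_stat_cutpoint(score, t, e, minprop=0.2)
        assert res.n_low >= 10 and res.n_high >= 10

    def test_selection_effect_inflates_null_statistic(self):
        """With no true association, the selected |z| exceeds 1.96 far more
        often than the nominal 5% — the documented selection effect."""
        rng = np.random.default_rng(5)
        exceed = 0
        reps = 200
        for _ in range(reps):
            score = rng.normal(size=200)
            t = rng.exponential(30, 200)
            c = rng.uniform(0, 60, 200)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            res = max_stat_cutpoint(score, time, event)
            exceed += res.max_stat > 1.96
        assert exceed / reps > 0.2

    def test_too_few_candidates_errors(self):
        with pytest.raises(ValueError, match="admissible|events"):
            max_stat_cutpoint([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 1], minprop=0.4)
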