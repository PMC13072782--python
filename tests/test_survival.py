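"""Unit tests for the survival engine: KM, log-rank, Cox, PH diagnostics."""

import numpy as np
import pandas as pd
import pytest

from markerdyn.cohort import CohortConfig, cohort_to_frame, generate_cohort
from markerdyn.survival import cox_fit, km_fit, logrank_test, schoenfeld_ph_test

from _oracles import efron_loglik, km_by_hand


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_all_events_hand_computation(self):
        km = km_fit([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(km.variance, [4 / 9 / 6, 1 / 9 * (1 / 6 + 1 / 2), 0.0])
        assert km.median == 2.0

    def test_mixed_censoring_hand_computation(self):
        # deaths at 1, 2, 4; censored at 2 and 5
        km = km_fit([1, 2, 2, 4, 5], [1, 0, 1, 1, 0])
        np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.3])
        np.testing.assert_allclose(
            km.variance,
            [0.64 / 20, 0.36 * (1 / 20 + 1 / 12), 0.09 * (1 / 20 + 1 / 12 + 1 / 2)],
        )
        assert km.median == 4.0

    def test_agrees_with_hand_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(5, 80), 0) + 1
        e = (rng.random(80) < 0.7).astype(int)
        km = km_fit(t, e)
        ot, os_, ov = km_by_hand(t, e)
        np.testing.assert_allclose(km.event_times, ot)
        np.testing.assert_allclose(km.survival, os_, atol=1e-12)
        np.testing.assert_allclose(km.variance, ov, atol=1e-12)

    def test_all_censored_curve_is_one_median_undefined(self):
        km = km_fit([2, 4, 6], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.median is None

    def test_single_subject_event(self):
        km = km_fit([5.0], [1])
        np.testing.assert_allclose(km.survival, [0.0])
        assert km.median == 5.0

    def test_risk_table_counts(self):
        km = km_fit([1, 2, 2, 4, 5], [1, 0, 1, 1, 0], risk_table_timepoints=[0, 2, 4.5])
        assert km.risk_table[0.0] == (5, 0)
        assert km.risk_table[2.0] == (4, 2)
        assert km.risk_table[4.5] == (1, 3)
        # at-risk counts never increase over timepoints
        at_risk = [v[0] for v in km.risk_table.values()]
        assert at_risk == sorted(at_risk, reverse=True)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_fit([], [])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_six_subject_hand_worked_table(self):
        # group A: events at 1, 3, censored 5; group B: events at 2, 4, 6.
        # By hand: O_A = 2, E_A = 1/2 + 2/5 + 1/2 + 1/3, V = 0.25 + 0.24
        # + 0.25 + 2/9 (hypergeometric variance at each event time).
        t = [1, 3, 5, 2, 4, 6]
        e = [1, 1, 0, 1, 1, 1]
        g = ["A", "A", "A", "B", "B", "B"]
        res = logrank_test(t, e, g)
        e_a = 0.5 + 0.4 + 0.5 + 1 / 3
        v = 0.25 + 0.24 + 0.25 + 2 / 9
        np.testing.assert_allclose(res.statistic, (2 - e_a) ** 2 / v, rtol=1e-10)
        np.testing.assert_allclose(res.observed, [2, 3])
        np.testing.assert_allclose(res.expected, [e_a, 5 - e_a], rtol=1e-12)

    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(3, 40) + 0.1
        e = (rng.random(40) < 0.8).astype(int)
        g = rng.integers(0, 2, 40)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(3)
        t = rng.exponential(3, 90) + 0.1
        e = (rng.random(90) < 0.7).astype(int)
        g = rng.integers(0, 3, 90)  # three groups
        res = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["A", "A"])


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


class TestCox:
    def test_toy_fixture_betas_match_oracle_loglik(self, cox_toy_fixtures):
        # pointwise check that the reported optimum beats nearby values of
        # the independently-coded partial likelihood (full grid equivalence
        # is exercised in the acceptance suite)
        for t, e, x in cox_toy_fixtures:
            fit = cox_fit(t, e, x)
            b = fit.coefficients[0]
            ll_hat = efron_loglik(b, t, e, x)
            assert fit.log_partial_likelihood == pytest.approx(ll_hat, abs=1e-9)
            for db in (-1e-4, 1e-4):
                assert efron_loglik(b + db, t, e, x) <= ll_hat + 1e-12

    def test_matches_lifelines_multivariate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 250
        X = rng.standard_normal((n, 3))
        t = rng.exponential(np.exp(-X @ np.array([0.6, -0.4, 0.0]))) + 1e-3
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(t, e, X)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = t, e
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coefficients, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors, ref.standard_errors_.values, atol=1e-6)
        assert fit.log_partial_likelihood >= ref.log_likelihood_ - 1e-8

    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(11)
        n = 800
        t = rng.exponential(5, n) + 0.01
        e = (rng.random(n) < 0.9).astype(int)
        x = rng.standard_normal(n)  # independent of outcome
        fit = cox_fit(t, e, x)
        assert abs(fit.coefficients[0]) < 2.5 * fit.standard_errors[0]

    def test_affine_equivariance_of_scale(self, cox_toy_fixtures):
        t, e, x = cox_toy_fixtures[4]
        a = cox_fit(t, e, x)
        b = cox_fit(t, e, 10.0 * x)
        assert b.coefficients[0] == pytest.approx(a.coefficients[0] / 10.0, rel=1e-6)
        assert b.log_partial_likelihood == pytest.approx(a.log_partial_likelihood, rel=1e-10)
        assert b.p_values[0] == pytest.approx(a.p_values[0], rel=1e-6)

    def test_aic_identity_and_ci_shape(self, cox_toy_fixtures):
        for t, e, x in cox_toy_fixtures:
            fit = cox_fit(t, e, x)
            assert fit.aic == -2.0 * fit.log_partial_likelihood + 2.0
            np.testing.assert_allclose(fit.hazard_ratios, np.exp(fit.coefficients))
            np.testing.assert_allclose(
                fit.hr_ci[:, 0],
                np.exp(fit.coefficients - 1.96 * fit.standard_errors),
                rtol=1e-3,
            )

    def test_complete_separation_flagged(self):
        # covariate perfectly orders the death times: monotone likelihood
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.ones(8, dtype=int)
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        fit = cox_fit(t, e, x)
        assert not fit.converged
        assert "separation" in fit.message or "monotone" in fit.message

    def test_zero_events_raises(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2, 3], [0, 0, 0], [0.0, 1, 0])

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError):
            cox_fit([1, 2, 3], [1, 1, 0], [2.0, 2, 2])


# ---------------------------------------------------------------------------
# Schoenfeld PH diagnostic
# ---------------------------------------------------------------------------


class TestSchoenfeld:
    def test_proportional_hazards_data_not_rejected(self):
        df = cohort_to_frame(
            generate_cohort(
                CohortConfig(
                    n_patients=300, seed=9, effect_type="threshold",
                    true_cutoff_pct=15.0, log_hazard_ratio=np.log(2.0),
                )
            )
        )
        from markerdyn.dynamics import marker_pct_change

        x = (marker_pct_change(df, "CEA") > 15.0).astype(float)
        res = schoenfeld_ph_test(df["os_time"], df["os_event"], x, names=["above"])
        assert res.defined
        assert res.p_values["above"] > 0.01  # PH holds by construction

    def test_crossing_hazards_detected(self):
        # group 1: Weibull shape 3 (late hazard); group 0: shape 0.6 (early)
        rng = np.random.default_rng(21)
        n = 300
        x = np.repeat([0.0, 1.0], n)
        t0 = 5 * rng.weibull(0.6, n)
        t1 = 5 * rng.weibull(3.0, n)
        t = np.concatenate([t0, t1]) + 1e-3
        e = np.ones(2 * n, dtype=int)
        res = schoenfeld_ph_test(t, e, x, names=["grp"])
        assert res.defined
        assert res.p_values["grp"] < 0.01

    def test_too_few_events_flagged_undefined(self):
        res = schoenfeld_ph_test([1, 2, 3, 4], [1, 0, 0, 0], [0.0, 1, 0, 1])
        assert not res.defined
        assert np.isnan(res.p_values["x0"])
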