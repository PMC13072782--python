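"""Tests for marker percentage changes, continuous Cox, spline linearity
check, inter-marker correlation, and time-dependent ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerdyn.cohort import CohortConfig, cohort_to_frame, generate_cohort
from markerdyn.dynamics import (
    continuous_cox_per10,
    marker_correlation,
    marker_pct_change,
    pct_change,
    spline_nonlinearity_test,
    td_roc,
)

from _oracles import mann_whitney_auc


class TestPctChange:
    def test_basic_arithmetic(self):
        assert pct_change(100, 100) == 0.0
        assert pct_change(200, 50) == -75.0
        assert pct_change(56.5, 99.8) == pytest.approx(76.637, abs=0.01)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            pct_change(0.0, 10.0)
        with pytest.raises(ValueError):
            pct_change(10.0, 0.0)

    @given(
        b=st.floats(0.1, 1e4), ratio=st.floats(0.01, 100.0), c=st.floats(0.01, 100.0)
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_common_rescaling(self, b, ratio, c):
        assert pct_change(c * b, c * b * ratio) == pytest.approx(
            pct_change(b, b * ratio), rel=1e-9, abs=1e-7
        )

    def test_bounded_below_by_minus_100(self):
        df = cohort_to_frame(generate_cohort(CohortConfig(n_patients=500, seed=1)))
        assert (marker_pct_change(df, "CEA") > -100).all()


class TestContinuousCox:
    def test_per10_equals_per1_to_the_tenth(self, threshold_cohort):
        res = continuous_cox_per10(threshold_cohort, "CEA", "OS")
        assert res.hr_per10 == pytest.approx(
            float(res.fit.hazard_ratios[0]) ** 10, rel=1e-10
        )

    def test_linear_effect_recovery(self):
        b = 0.002
        df = cohort_to_frame(
            generate_cohort(
                CohortConfig(n_patients=500, seed=77, effect_type="linear",
                             log_hazard_ratio=b)
            )
        )
        res = continuous_cox_per10(df, "CEA", "OS")
        se = float(res.fit.standard_errors[0])
        assert abs(float(res.fit.coefficients[0]) - b) <= 2.5 * se
        assert res.hr_per10 > 1.0

    def test_null_cohort_ci_covers_one(self, null_cohort):
        res = continuous_cox_per10(null_cohort, "CEA", "OS")
        lo, hi = res.hr_per10_ci
        assert lo < 1.0 < hi


class TestSplineNonlinearity:
    def test_threshold_effect_detected(self):
        df = cohort_to_frame(
            generate_cohort(
                CohortConfig(n_patients=500, seed=91, effect_type="threshold",
                             true_cutoff_pct=15.0, log_hazard_ratio=np.log(3.0))
            )
        )
        res = spline_nonlinearity_test(df, "CEA", "OS")
        assert res.defined and res.p_value < 0.05

    def test_too_few_events_flagged(self, threshold_cohort):
        df = threshold_cohort.copy()
        df["os_event"] = 0
        df.loc[df.index[:5], "os_event"] = 1
        res = spline_nonlinearity_test(df, "CEA", "OS")
        assert not res.defined and np.isnan(res.p_value)

    def test_constant_change_raises(self, threshold_cohort):
        df = threshold_cohort.copy()
        df["cea_baseline"] = 100.0
        df["cea_post"] = 150.0  # identical +50% change for everyone
        with pytest.raises(ValueError):
            spline_nonlinearity_test(df, "CEA", "OS")


class TestMarkerCorrelation:
    def _df_from_changes(self, cea, ca):
        n = len(cea)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "sex": "male", "sidedness": "left", "ras_status": "mutant",
            "treatment_line": "third",
            "cea_baseline": 100.0, "cea_post": 100.0 * (1 + np.asarray(cea) / 100),
            "ca199_baseline": 100.0, "ca199_post": 100.0 * (1 + np.asarray(ca) / 100),
            "pfs_time": 1.0, "pfs_event": 1, "os_time": 2.0, "os_event": 1,
        })

    def test_identical_changes_rho_one(self):
        ch = [10.0, -5.0, 40.0, 3.0, 88.0]
        res = marker_correlation(self._df_from_changes(ch, ch))
        assert res.rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        cea = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = marker_correlation(self._df_from_changes(cea, cea[::-1]))
        assert res.rho == pytest.approx(-1.0)

    def test_independent_changes_rho_near_zero(self):
        small = 0
        for rep in range(10):
            df = cohort_to_frame(
                generate_cohort(CohortConfig(n_patients=61, seed=500 + rep))
            )
            if abs(marker_correlation(df).rho) < 0.3:
                small += 1
        assert small >= 8

    def test_tiny_sample_undefined(self):
        res = marker_correlation(self._df_from_changes([1.0, 2.0], [3.0, 4.0]))
        assert not res.defined


class TestTimeDependentROC:
    def test_reduces_to_mann_whitney_without_censoring(self):
        cfg = CohortConfig(
            n_patients=400, seed=3, censoring_rate=0.0, admin_censor_time=1e9,
            effect_type="linear", log_hazard_ratio=0.003,
        )
        df = cohort_to_frame(generate_cohort(cfg))
        roc = td_roc(df, "CEA", "OS", horizon=6.0)
        x = marker_pct_change(df, "CEA")
        t = df["os_time"].to_numpy()
        case = t <= 6.0
        assert roc.auc == pytest.approx(mann_whitney_auc(x[case], x[~case]), abs=1e-12)

    def test_perfect_score_gives_auc_one(self):
        rng = np.random.default_rng(4)
        n = 60
        t = np.concatenate([rng.uniform(1, 5, 30), rng.uniform(8, 20, 30)])
        df = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "sex": "male", "sidedness": "left", "ras_status": "mutant",
            "treatment_line": "third",
            "cea_baseline": 100.0,
            "cea_post": np.where(t <= 6.0, 300.0, 50.0),  # score = event indicator
            "ca199_baseline": 100.0, "ca199_post": 100.0,
            "pfs_time": t, "pfs_event": 1, "os_time": t, "os_event": 1,
        })
        roc = td_roc(df, "CEA", "OS", horizon=6.0)
        assert roc.auc == pytest.approx(1.0)

    def test_null_score_auc_near_half(self, null_cohort):
        roc = td_roc(null_cohort, "CEA", "OS", horizon=6.0)
        assert abs(roc.auc - 0.5) < 0.08

    def test_curve_spans_unit_square(self, threshold_cohort):
        roc = td_roc(threshold_cohort, "CEA", "OS", horizon=6.0)
        assert roc.sensitivity[0] == 0.0 and roc.specificity[0] == 1.0
        assert roc.sensitivity[-1] == 1.0 and roc.specificity[-1] == 0.0

    def test_matches_scikit_survival_ipcw_auc(self, threshold_cohort):
        sksurv = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv

        df = threshold_cohort
        x = marker_pct_change(df, "CEA")
        y = Surv.from_arrays(
            event=df["os_event"].astype(bool), time=df["os_time"]
        )
        auc, _ = sksurv.cumulative_dynamic_auc(y, y, x, times=[6.0])
        roc = td_roc(df, "CEA", "OS", horizon=6.0)
        assert roc.auc == pytest.approx(float(auc[0]), abs=0.01)

    def test_no_controls_flagged_undefined(self):
        df = pd.DataFrame({
            "patient_id": ["a", "b", "c"],
            "sex": "male", "sidedness": "left", "ras_status": "mutant",
            "treatment_line": "third",
            "cea_baseline": 100.0, "cea_post": [150.0, 120.0, 80.0],
            "ca199_baseline": 100.0, "ca199_post": 100.0,
            "pfs_time": [1.0, 2.0, 3.0], "pfs_event": 1,
            "os_time": [1.0, 2.0, 3.0], "os_event": 1,
        })
        roc = td_roc(df, "CEA", "OS", horizon=6.0)
        assert not roc.defined and np.isnan(roc.auc)
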