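import numpy as np
import pandas as pd
import pytest

from markerdyn.cohort import CohortConfig, cohort_to_frame, generate_cohort


# ---------------------------------------------------------------------------
# small survival fixtures (hand-checkable)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def cox_toy_fixtures():
    """Single-covariate datasets with n <= 8 covering ties and censoring."""
    return [
        # untied, fully observed
        (np.array([1.0, 2, 3, 4, 5, 6]), np.array([1, 1, 1, 1, 1, 1]),
         np.array([0.0, 1, 0, 1, 0, 1])),
        # censoring
        (np.array([1.0, 2, 3, 4, 5, 6]), np.array([1, 0, 1, 1, 0, 1]),
         np.array([1.0, 1, 0, 0, 1, 0])),
        # heavy ties
        (np.array([1.0, 1, 1, 2, 2, 3, 3, 3]), np.array([1, 1, 0, 1, 1, 1, 0, 1]),
         np.array([0.0, 1, 1, 0, 1, 0, 1, 1])),
        # censored subject at an event time (stays in that risk set)
        (np.array([2.0, 2, 2, 4, 4, 6]), np.array([1, 1, 0, 1, 0, 1]),
         np.array([1.0, 0, 1, 0, 1, 1])),
        # continuous covariate
        (np.array([3.0, 1, 4, 1.5, 5, 2.5, 6, 2]), np.array([1, 1, 0, 1, 1, 1, 1, 0]),
         np.array([-1.2, 0.4, 2.0, -0.5, 1.1, 0.0, -2.0, 0.7])),
    ]


def make_cohort(**overrides) -> pd.DataFrame:
    return cohort_to_frame(generate_cohort(CohortConfig(**overrides)))


@pytest.fixture(scope="session")
def threshold_cohort():
    """n=500 cohort with a true +15% CEA threshold effect, group HR 2."""
    return make_cohort(
        n_patients=500, seed=42, effect_type="threshold",
        true_cutoff_pct=15.0, log_hazard_ratio=np.log(2.0),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """n=500 cohort with no marker-survival association."""
    return make_cohort(n_patients=500, seed=43, effect_type="null")


@pytest.fixture(scope="session")
def study_scale_cohort():
    """n=61 cohort with a strong threshold effect (study-sized)."""
    return make_cohort(
        n_patients=61, seed=44, effect_type="threshold",
        true_cutoff_pct=15.0, log_hazard_ratio=np.log(3.0),
    )


def make_gap_cohort(n_per_group: int = 15, seed: int = 0) -> pd.DataFrame:
    """Cohort whose CEA changes leave a wide empty gap around the effective
    cutoff, with a drastic survival difference between the two clusters.

    Favorable cluster: changes in [-40, -20], long survival; unfavorable:
    changes in [+40, +60], short survival.  Any cutoff re-derived from a
    leave-one-out or bootstrap subset lands inside the gap, so individual
    classifications are perfectly stable.  One survival outlier per cluster
    keeps the dichotomized Cox likelihood bounded (no complete separation);
    survival times are otherwise deterministic so the optimum sits squarely
    at the gap split rather than drifting on noise.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    changes = np.concatenate([
        np.sort(rng.uniform(-40, -20, n_per_group)),
        np.sort(rng.uniform(40, 60, n_per_group)),
    ])
    # the outliers sit at the extreme ends of each cluster's change range so
    # no cutoff can isolate them from their cluster
    long = np.linspace(10.0, 24.0, n_per_group)
    long[0] = 2.0  # early death at the most-negative change
    short = np.linspace(1.0, 8.0, n_per_group)
    short[-1] = 15.0  # long survivor at the most-positive change
    os_time = np.concatenate([long, short])
    pfs_time = 0.6 * os_time
    baseline = np.full(n, 100.0)
    return pd.DataFrame({
        "patient_id": [f"G{i:03d}" for i in range(n)],
        "sex": ["male", "female"] * n_per_group,
        "sidedness": ["left"] * n,
        "ras_status": ["mutant"] * n,
        "treatment_line": ["third"] * n,
        "cea_baseline": baseline,
        "cea_post": baseline * (1 + changes / 100.0),
        "ca199_baseline": baseline,
        "ca199_post": baseline * (1 + changes / 100.0),
        "pfs_time": pfs_time,
        "pfs_event": 1,
        "os_time": os_time,
        "os_event": 1,
    })
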