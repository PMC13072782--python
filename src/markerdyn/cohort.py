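"""Synthetic patient cohorts with the statistical structure of serial
tumor-marker survival studies in late-line metastatic colorectal cancer.

Each patient carries baseline and post-cycle CEA (ng/mL) and CA-19-9 (U/mL)
levels, categorical covariates, and two right-censored endpoints (PFS, OS, in
months).  Marker levels are log-normal; the on-treatment percentage change
is a shifted log-normal on the ratio post/baseline, reproducing the heavy
right skew of real marker kinetics (median increases near +80-95% with
interquartile ranges spanning decreases).  Survival follows a Weibull
proportional-hazards model whose log-hazard may depend on the marker change
through a step (threshold), a linear term, or not at all.

Default parameters are calibrated to the cohort the package emulates:
median baseline CEA 56.5 ng/mL (IQR 17.9-247), CA-19-9 58.1 U/mL
(IQR 24.4-272), median changes +76.6% / +94.5%, 61 patients, ~50 months of
maximum follow-up.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MARKERS",
    "MARKER_COLUMNS",
    "ConfigError",
    "SchemaError",
    "CohortValidationError",
    "CohortConfig",
    "PatientRecord",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_records",
    "as_cohort_frame",
    "read_cohort_csv",
    "write_cohort_csv",
]

MARKERS = ("CEA", "CA19_9")
MARKER_COLUMNS = {
    "CEA": ("cea_baseline", "cea_post"),
    "CA19_9": ("ca199_baseline", "ca199_post"),
}

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "sidedness",
    "ras_status",
    "treatment_line",
    "cea_baseline",
    "cea_post",
    "ca199_baseline",
    "ca199_post",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]

_SIDEDNESS_LEVELS = ("left", "rectum", "right")

# Normal quantile of 0.75; converts a log-scale IQR ratio to a sigma.
_Z75 = 0.6744897501960817


class ConfigError(ValueError):
    """Invalid cohort configuration; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class SchemaError(ValueError):
    """Cohort CSV is missing a required column."""


class CohortValidationError(ValueError):
    """Cohort rows violate value constraints; ``rows`` lists 0-based indices."""

    def __init__(self, message: str, rows):
        self.rows = list(rows)
        super().__init__(f"{message} (rows: {self.rows})")


def _default_log_medians() -> dict:
    return {"CEA": math.log(56.5), "CA19_9": math.log(58.1)}


def _default_log_sigmas() -> dict:
    # log-normal sigma from the IQR ratio: ln(q75/q25) / (2 * z_{0.75})
    return {
        "CEA": math.log(247.0 / 17.9) / (2 * _Z75),
        "CA19_9": math.log(272.0 / 24.4) / (2 * _Z75),
    }


def _default_change_medians() -> dict:
    return {"CEA": 76.6, "CA19_9": 94.5}


def _default_change_sigmas() -> dict:
    return {"CEA": 1.0, "CA19_9": 1.0}


def _default_mixture() -> dict:
    return {
        "responder_weight": 0.3,
        "responder_median_pct": -30.0,
        "responder_log_sigma": 0.4,
        "progressor_median_pct": 150.0,
        "progressor_log_sigma": 0.8,
    }


def _default_prevalences() -> dict:
    return {"male": 0.607, "ras_mutant": 0.655, "third_line": 0.59}


def _default_sidedness() -> dict:
    return {"left": 0.639, "rectum": 0.197, "right": 0.164}


@dataclass
class CohortConfig:
    """Generator settings; defaults emulate the study cohort structure.

    ``log_hazard_ratio`` is per group in threshold mode and per 1 percentage
    point of marker change in linear mode.  Times are in months throughout.
    """

    n_patients: int = 61
    seed: int = 0
    marker_log_median: dict = field(default_factory=_default_log_medians)
    marker_log_sigma: dict = field(default_factory=_default_log_sigmas)
    change_model: str = "lognormal-shift"  # or "two-component"
    change_median_pct: dict = field(default_factory=_default_change_medians)
    change_log_sigma: dict = field(default_factory=_default_change_sigmas)
    change_mixture: dict = field(default_factory=_default_mixture)
    effect_type: str = "linear"  # {"threshold", "linear", "null"}
    effect_marker: str = "CEA"
    true_cutoff_pct: float = 15.0
    log_hazard_ratio: float = 7e-4
    baseline_hazard_scale: float = 12.0  # months (death-time Weibull scale)
    baseline_hazard_shape: float = 1.1
    progression_scale_ratio: float = 0.5
    frailty_sigma: float = 0.0
    censoring_rate: float = 0.05
    admin_censor_time: float = 50.0
    covariate_prevalences: dict = field(default_factory=_default_prevalences)
    sidedness_probs: dict = field(default_factory=_default_sidedness)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 2:
            raise ConfigError("n_patients", "must be an integer >= 2")
        for m in MARKERS:
            if m not in self.marker_log_median:
                raise ConfigError("marker_log_median", f"missing marker {m}")
            if self.marker_log_sigma.get(m, 0.0) <= 0:
                raise ConfigError("marker_log_sigma", f"sigma for {m} must be > 0")
            if self.change_model == "lognormal-shift":
                if self.change_median_pct.get(m, 0.0) <= -100:
                    raise ConfigError("change_median_pct", f"{m} must exceed -100")
                if self.change_log_sigma.get(m, 0.0) <= 0:
                    raise ConfigError("change_log_sigma", f"sigma for {m} must be > 0")
        if self.change_model not in ("lognormal-shift", "two-component"):
            raise ConfigError("change_model", "must be lognormal-shift or two-component")
        if self.effect_type not in ("threshold", "linear", "null"):
            raise ConfigError("effect_type", "must be threshold, linear, or null")
        if self.effect_marker not in MARKERS:
            raise ConfigError("effect_marker", f"must be one of {MARKERS}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError("censoring_rate", "must lie in [0, 1)")
        if self.admin_censor_time <= 0:
            raise ConfigError("admin_censor_time", "must be > 0")
        if self.baseline_hazard_scale <= 0:
            raise ConfigError("baseline_hazard_scale", "must be > 0")
        if self.baseline_hazard_shape <= 0:
            raise ConfigError("baseline_hazard_shape", "must be > 0")
        if not 0 < self.progression_scale_ratio <= 1.0:
            raise ConfigError("progression_scale_ratio", "must lie in (0, 1]")
        if self.frailty_sigma < 0:
            raise ConfigError("frailty_sigma", "must be >= 0")
        for k, v in self.covariate_prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError("covariate_prevalences", f"{k} not in [0, 1]")
        if abs(sum(self.sidedness_probs.get(s, 0.0) for s in _SIDEDNESS_LEVELS) - 1.0) > 1e-6:
            raise ConfigError("sidedness_probs", "probabilities must sum to 1")
        if self.effect_type == "threshold":
            # cutoff must be interior to the change distribution (within the
            # central 99.9% band), otherwise one stratum is empty w.p. ~1
            m = self.effect_marker
            if self.change_model == "lognormal-shift":
                med = 1.0 + self.change_median_pct[m] / 100.0
                sig = self.change_log_sigma[m]
                lo = 100.0 * (med * math.exp(-3.29 * sig) - 1.0)
                hi = 100.0 * (med * math.exp(3.29 * sig) - 1.0)
                if not lo < self.true_cutoff_pct < hi:
                    raise ConfigError(
                        "true_cutoff_pct",
                        f"must lie inside the change range ({lo:.1f}, {hi:.1f})",
                    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        base = cls()
        merged = dataclasses.asdict(base)
        for k, v in d.items():
            if k not in merged:
                raise ConfigError(k, "unknown configuration field")
            if isinstance(merged[k], dict) and isinstance(v, dict):
                merged[k] = {**merged[k], **v}
            else:
                merged[k] = v
        return cls(**merged)


@dataclass
class PatientRecord:
    patient_id: str
    sex: str
    sidedness: str
    ras_status: str
    treatment_line: str
    cea_baseline: float
    cea_post: float
    ca199_baseline: float
    ca199_post: float
    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int


def _draw_changes(rng: np.random.Generator, cfg: CohortConfig, marker: str, n: int) -> np.ndarray:
    """Percentage change Delta with post = baseline * (1 + Delta/100) > 0."""
    if cfg.change_model == "lognormal-shift":
        med_ratio = 1.0 + cfg.change_median_pct[marker] / 100.0
        ratio = med_ratio * np.exp(cfg.change_log_sigma[marker] * rng.standard_normal(n))
    else:
        mix = cfg.change_mixture
        resp = rng.random(n) < mix["responder_weight"]
        med = np.where(
            resp,
            1.0 + mix["responder_median_pct"] / 100.0,
            1.0 + mix["progressor_median_pct"] / 100.0,
        )
        sig = np.where(resp, mix["responder_log_sigma"], mix["progressor_log_sigma"])
        ratio = med * np.exp(sig * rng.standard_normal(n))
    return 100.0 * (ratio - 1.0)


def _tune_censoring_rate(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate theta with mean P(C < T | T=t_i) = target."""
    if target <= 0:
        return 0.0

    def f(theta):
        return float(np.mean(1.0 - np.exp(-theta * event_times))) - target

    lo, hi = 1e-12, 1e-12
    while f(hi := hi * 10) < 0:
        if hi > 1e8:
            return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw ``config.n_patients`` synthetic patients; deterministic given seed.

    Survival model: Weibull(shape k, scale lambda) baseline for the death
    time, scale ``progression_scale_ratio * lambda`` for the progression
    time, shared individual log-hazard eta from the configured effect (plus
    optional log-normal frailty).  PFS = min(progression, death); OS = death.
    Censoring = min(Exponential tuned to ``censoring_rate``, administrative
    cutoff), shared by both endpoints.
    """
    config.validate()
    cfg = config
    n = int(cfg.n_patients)
    rng = np.random.default_rng(cfg.seed)

    prev = cfg.covariate_prevalences
    sex = np.where(rng.random(n) < prev.get("male", 0.5), "male", "female")
    side_p = [cfg.sidedness_probs[s] for s in _SIDEDNESS_LEVELS]
    sidedness = rng.choice(np.array(_SIDEDNESS_LEVELS), size=n, p=side_p)
    ras = np.where(rng.random(n) < prev.get("ras_mutant", 0.5), "mutant", "wild-type")
    line = np.where(rng.random(n) < prev.get("third_line", 0.5), "third", "fourth-plus")

    baselines: dict[str, np.ndarray] = {}
    posts: dict[str, np.ndarray] = {}
    changes: dict[str, np.ndarray] = {}
    for m in MARKERS:
        baselines[m] = np.exp(
            cfg.marker_log_median[m] + cfg.marker_log_sigma[m] * rng.standard_normal(n)
        )
        changes[m] = _draw_changes(rng, cfg, m, n)
        posts[m] = baselines[m] * (1.0 + changes[m] / 100.0)

    delta = changes[cfg.effect_marker]
    if cfg.effect_type == "threshold":
        eta = cfg.log_hazard_ratio * (delta > cfg.true_cutoff_pct).astype(float)
    elif cfg.effect_type == "linear":
        eta = cfg.log_hazard_ratio * delta
    else:
        eta = np.zeros(n)
    if cfg.frailty_sigma > 0:
        eta = eta + cfg.frailty_sigma * rng.standard_normal(n)

    k = cfg.baseline_hazard_shape
    lam = cfg.baseline_hazard_scale
    t_death = lam * (rng.exponential(1.0, n) * np.exp(-eta)) ** (1.0 / k)
    t_prog = (cfg.progression_scale_ratio * lam) * (
        rng.exponential(1.0, n) * np.exp(-eta)
    ) ** (1.0 / k)

    theta = _tune_censoring_rate(t_death, cfg.censoring_rate)
    c_exp = rng.exponential(1.0 / theta, n) if theta > 0 else np.full(n, np.inf)
    c_time = np.minimum(c_exp, cfg.admin_censor_time)

    os_time = np.minimum(t_death, c_time)
    os_event = (t_death <= c_time).astype(int)
    pfs_latent = np.minimum(t_prog, t_death)
    pfs_time = np.minimum(pfs_latent, c_time)
    pfs_event = (pfs_latent <= c_time).astype(int)

    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                sex=str(sex[i]),
                sidedness=str(sidedness[i]),
                ras_status=str(ras[i]),
                treatment_line=str(line[i]),
                cea_baseline=float(baselines["CEA"][i]),
                cea_post=float(posts["CEA"][i]),
                ca199_baseline=float(baselines["CA19_9"][i]),
                ca199_post=float(posts["CA19_9"][i]),
                pfs_time=float(pfs_time[i]),
                pfs_event=int(pfs_event[i]),
                os_time=float(os_time[i]),
                os_event=int(os_event[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# container conversion and CSV round-trip
# ---------------------------------------------------------------------------


def cohort_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=COHORT_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    _validate_frame(df)
    return [PatientRecord(**{c: row[c] for c in COHORT_COLUMNS}) for row in df.to_dict("records")]


def as_cohort_frame(records_or_frame) -> pd.DataFrame:
    """Coerce a list of PatientRecord or a DataFrame to the canonical frame."""
    if isinstance(records_or_frame, pd.DataFrame):
        _validate_frame(records_or_frame)
        return records_or_frame.reset_index(drop=True)
    return cohort_to_frame(list(records_or_frame))


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad_rows: set[int] = set()
    for col in ["cea_baseline", "cea_post", "ca199_baseline", "ca199_post", "pfs_time", "os_time"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        bad_rows.update(np.flatnonzero(bad.to_numpy()).tolist())
    for col in ["pfs_event", "os_event"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        bad_rows.update(np.flatnonzero(bad.to_numpy()).tolist())
    if bad_rows:
        raise CohortValidationError(
            "non-positive or missing marker/time values, or non-binary event flags",
            sorted(bad_rows),
        )


def write_cohort_csv(records, path) -> None:
    """Write the cohort as UTF-8 CSV with '.' decimals (full float precision)."""
    df = as_cohort_frame(records)
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV; schema and value constraints are enforced."""
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ["pfs_event", "os_event"]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    recs = frame_to_records(df)
    for r in recs:
        r.pfs_event = int(r.pfs_event)
        r.os_event = int(r.os_event)
    return recs
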