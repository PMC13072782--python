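"""End-to-end analysis pipeline.

Sequences: cohort load/generation -> percentage changes -> continuous Cox +
spline linearity check + inter-marker correlation -> per-endpoint threshold
scans and joint cutoff selection -> Kaplan-Meier / log-rank stratification
with risk tables -> bootstrap stability + LOOCV concordance -> 6-month
time-dependent ROC -> univariable/multivariable regression tables, and
emits a JSON report plus CSV artifacts (scan profiles, bootstrap cutoff
vectors, LOOCV tables, KM curves).

One analysis seed governs every stochastic stage through a stage-name ->
child-seed derivation (SHA-256 of ``"{seed}:{stage}"``), so adding a stage
never perturbs the draws of the others, and a rerun at the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    MARKERS,
    as_cohort_frame,
    cohort_to_frame,
    generate_cohort,
    read_cohort_csv,
)
from .cutpoints import GridSpec, scan_thresholds, select_cutoff, stratify
from .dynamics import (
    continuous_cox_per10,
    endpoint_arrays,
    marker_correlation,
    marker_pct_change,
    spline_nonlinearity_test,
    td_roc,
)
from .regression import DEFAULT_VARIABLES, Variable, multivariable_model, univariable_screen
from .survival import km_fit, logrank_test
from .validation import bootstrap_stability, loocv_concordance

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline", "child_seed"]

log = logging.getLogger("markerdyn")


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from the analysis seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class AnalysisConfig:
    input_path: str | None = None
    cohort: CohortConfig | None = None  # used when input_path is None
    markers: list[str] = field(default_factory=lambda: list(MARKERS))
    endpoints: list[str] = field(default_factory=lambda: ["PFS", "OS"])
    grid_mode: str = "observed"
    grid_lower: float = -50.0
    grid_upper: float = 50.0
    grid_step: float = 5.0
    min_group: int = 10
    alpha: float = 0.05
    enter_p: float = 0.10
    stay_p: float = 0.05
    n_bootstrap: int = 1000
    roc_horizon: float = 6.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        for name in ("alpha", "enter_p", "stay_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.roc_horizon <= 0:
            raise ValueError("roc_horizon must be > 0")
        for m in self.markers:
            if m not in MARKERS:
                raise ValueError(f"unknown marker {m!r}")
        for ep in self.endpoints:
            if ep not in ("PFS", "OS"):
                raise ValueError(f"unknown endpoint {ep!r}")

    def grid(self) -> GridSpec:
        return GridSpec(self.grid_mode, self.grid_lower, self.grid_upper, self.grid_step)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        cohort = d.pop("cohort", None)
        cfg = cls(**d)
        if cohort is not None:
            cfg.cohort = CohortConfig.from_dict(cohort)
        return cfg


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    cohort: pd.DataFrame
    report: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# JSON serialization with explicit float precision
# ---------------------------------------------------------------------------


def _jsonify(obj, sig: int = 10):
    """Recursively convert to JSON-safe values, floats at 10 significant
    digits (deterministic across reruns)."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v, sig) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v, sig) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if np.isnan(x):
            return None
        if np.isinf(x):
            return "inf" if x > 0 else "-inf"
        return float(f"{x:.{sig}g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _quartiles(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": med, "q1": q1, "q3": q3}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Run the full analysis; returns the report and writes artifacts.

    When ``config.input_path`` is unset a synthetic cohort is generated from
    ``config.cohort`` (defaults if omitted) with its seed derived from the
    analysis seed, so the whole run is governed by ``config.seed``.
    """
    t_start = _stage("cohort")
    if config.input_path is not None:
        records = read_cohort_csv(config.input_path)
        df = as_cohort_frame(records)
        cohort_cfg = None
    else:
        cohort_cfg = config.cohort if config.cohort is not None else CohortConfig()
        cohort_cfg = dataclasses.replace(cohort_cfg, seed=child_seed(config.seed, "cohort"))
        df = cohort_to_frame(generate_cohort(cohort_cfg))
    log.info("cohort ready: n=%d (%.2fs)", len(df), time.perf_counter() - t_start)

    grid = config.grid()
    report: dict = {
        "schema_version": 1,
        "software": {"package": "markerdyn", "version": __version__},
        "config": _config_dict(config, cohort_cfg),
        "seed": config.seed,
    }

    # ---- cohort summary -------------------------------------------------
    summary: dict = {"n_patients": len(df)}
    for m in config.markers:
        from .cohort import MARKER_COLUMNS

        b_col, p_col = MARKER_COLUMNS[m]
        summary[m] = {
            "baseline": _quartiles(df[b_col].to_numpy()),
            "post": _quartiles(df[p_col].to_numpy()),
            "pct_change": _quartiles(marker_pct_change(df, m)),
        }
    for ep in config.endpoints:
        t, e = endpoint_arrays(df, ep)
        summary[ep] = {"n_events": int(e.sum()), "censoring_fraction": float(1 - e.mean())}
    report["cohort_summary"] = summary

    # ---- continuous associations ---------------------------------------
    _stage("continuous")
    cont: dict = {}
    for m in config.markers:
        cont[m] = {}
        for ep in config.endpoints:
            r = continuous_cox_per10(df, m, ep)
            s = spline_nonlinearity_test(df, m, ep)
            cont[m][ep] = {
                "hr_per10": r.hr_per10,
                "hr_per10_ci": list(r.hr_per10_ci),
                "p_value": r.p_value,
                "nonlinearity_p": s.p_value if s.defined else None,
            }
    report["continuous_cox"] = cont
    if set(config.markers) == set(MARKERS):
        corr = marker_correlation(df)
        report["marker_correlation"] = {"spearman_rho": corr.rho, "p_value": corr.p_value}

    # ---- threshold scans and joint selection ----------------------------
    _stage("threshold_scan")
    scans: dict = {}
    selected: dict = {}
    scan_objs: dict = {}
    for m in config.markers:
        scans[m] = {}
        per_ep = {}
        for ep in config.endpoints:
            scan = scan_thresholds(
                df, m, ep, grid=grid, min_group=config.min_group, alpha=config.alpha
            )
            per_ep[ep] = scan
            scans[m][ep] = {
                "selected_cutoff": scan.selected_cutoff,
                "n_candidates": len(scan.candidates),
                "n_admissible": sum(c.admissible for c in scan.candidates),
                "selection_trace": scan.selection_trace,
            }
        scan_objs[m] = per_ep
        if "PFS" in per_ep and "OS" in per_ep:
            sel = select_cutoff(per_ep["PFS"], per_ep["OS"])
            selected[m] = {"cutoff": sel.cutoff, "trace": sel.trace}
        else:
            only = per_ep[config.endpoints[0]]
            selected[m] = {
                "cutoff": only.selected_cutoff,
                "trace": ["single-endpoint selection"] + only.selection_trace,
            }
    report["threshold_scans"] = scans
    report["selected_cutoffs"] = selected

    # ---- KM / log-rank by stratum ---------------------------------------
    _stage("km_stratified")
    km_section: dict = {}
    km_frames: dict = {}
    for m in config.markers:
        cutoff = selected[m]["cutoff"]
        km_section[m] = {}
        if cutoff is None:
            continue
        labels, _excluded = stratify(df, m, cutoff)
        lab_arr = labels.reindex(df["patient_id"]).to_numpy()
        for ep in config.endpoints:
            t, e = endpoint_arrays(df, ep)
            max_t = float(np.ceil(t.max()))
            tps = list(np.arange(0.0, max_t + 6.0, 6.0))
            groups_out = {}
            rows = []
            for lab in ("favorable", "unfavorable"):
                mask = lab_arr == lab
                if mask.sum() == 0:
                    continue
                curve = km_fit(t[mask], e[mask], risk_table_timepoints=tps)
                groups_out[lab] = {
                    "n": int(mask.sum()),
                    "median": curve.median,
                    "median_ci": list(curve.median_ci),
                    "risk_table": {str(k): list(v) for k, v in curve.risk_table.items()},
                }
                rows.append(
                    pd.DataFrame(
                        {
                            "group": lab,
                            "time": curve.event_times,
                            "survival": curve.survival,
                            "variance": curve.variance,
                        }
                    )
                )
            lr = logrank_test(t, e, lab_arr)
            km_section[m][ep] = {
                "cutoff": cutoff,
                "groups": groups_out,
                "logrank_statistic": lr.statistic,
                "logrank_p": lr.p_value,
            }
            km_frames[(m, ep)] = (
                pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
            )
    report["km_stratified"] = km_section

    # ---- internal validation --------------------------------------------
    _stage("validation")
    boot_section: dict = {}
    loocv_section: dict = {}
    boot_objs: dict = {}
    loocv_objs: dict = {}
    for m in config.markers:
        boot_section[m] = {}
        loocv_section[m] = {}
        for ep in config.endpoints:
            if scan_objs[m][ep].selected_cutoff is None:
                boot_section[m][ep] = None
                loocv_section[m][ep] = None
                continue
            bs = bootstrap_stability(
                df,
                m,
                ep,
                grid=grid,
                min_group=config.min_group,
                alpha=config.alpha,
                n_iter=config.n_bootstrap,
                seed=child_seed(config.seed, f"bootstrap:{m}:{ep}"),
            )
            boot_objs[(m, ep)] = bs
            boot_section[m][ep] = {
                "original_cutoff": bs.original_cutoff,
                "n_iterations": bs.n_iterations,
                "n_failed": bs.n_failed,
                "prop_within_window": bs.prop_within_window,
                "window_halfwidth": bs.window_halfwidth,
                "median": bs.median,
                "mean": bs.mean,
                "iqr": list(bs.iqr),
                "ci95": list(bs.ci95),
            }
            lv = loocv_concordance(
                df, m, ep, grid=grid, min_group=config.min_group, alpha=config.alpha
            )
            loocv_objs[(m, ep)] = lv
            loocv_section[m][ep] = {
                "original_cutoff": lv.original_cutoff,
                "concordance_pct": lv.concordance_pct,
                "n_unclassifiable": lv.n_unclassifiable,
            }
    report["bootstrap_stability"] = boot_section
    report["loocv"] = loocv_section

    # ---- time-dependent ROC ----------------------------------------------
    _stage("td_roc")
    roc_section: dict = {}
    for m in config.markers:
        roc_section[m] = {}
        for ep in config.endpoints:
            roc = td_roc(df, m, ep, horizon=config.roc_horizon)
            roc_section[m][ep] = {
                "horizon": roc.horizon,
                "auc": roc.auc if roc.defined else None,
                "n_cases": roc.n_cases,
                "n_controls": roc.n_controls,
            }
    report["td_roc"] = roc_section

    # ---- regression tables ------------------------------------------------
    _stage("regression")
    marker_vars: list[Variable] = []
    df_reg = df.copy()
    for m in config.markers:
        cutoff = selected[m]["cutoff"]
        if cutoff is None:
            continue
        col = f"{m.lower()}_above_cutoff"
        df_reg[col] = (marker_pct_change(df, m) > cutoff).astype(float)
        marker_vars.append(Variable(f"{m}_cutoff", col, "numeric"))
    reg_section: dict = {}
    for ep in config.endpoints:
        variables = DEFAULT_VARIABLES() + marker_vars
        uni = univariable_screen(df_reg, variables, ep, enter_p=config.enter_p)
        screened = [v for v in variables if v.name in uni.passed]
        ep_out = {
            "univariable": uni.to_frame().to_dict("records"),
            "screen_passed": uni.passed,
            "screen_excluded": uni.excluded,
        }
        if marker_vars or screened:
            for mode in ("backward", "forced-full"):
                try:
                    multi = multivariable_model(
                        df_reg, screened, marker_vars, ep, stay_p=config.stay_p, mode=mode
                    )
                    ep_out[mode] = {
                        "table": multi.to_frame().to_dict("records"),
                        "eliminated": multi.eliminated,
                    }
                except Exception as exc:  # declared non-convergence propagates as text
                    ep_out[mode] = {"error": str(exc)}
        reg_section[ep] = ep_out
    report["regression"] = reg_section

    # ---- artifacts --------------------------------------------------------
    artifacts: dict[str, Path] = {}
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.json"
        report_path.write_text(
            json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        artifacts["report"] = report_path
        for m in config.markers:
            for ep in config.endpoints:
                scan = scan_objs[m][ep]
                p = out / f"scan_{m}_{ep}.csv"
                scan.to_frame().to_csv(p, index=False, float_format="%.10g")
                artifacts[f"scan_{m}_{ep}"] = p
                if (m, ep) in boot_objs:
                    p = out / f"bootstrap_{m}_{ep}.csv"
                    pd.DataFrame({"cutoff": boot_objs[(m, ep)].cutoffs}).to_csv(
                        p, index=False, float_format="%.10g"
                    )
                    artifacts[f"bootstrap_{m}_{ep}"] = p
                if (m, ep) in loocv_objs:
                    p = out / f"loocv_{m}_{ep}.csv"
                    loocv_objs[(m, ep)].per_patient.to_csv(p, index=False, float_format="%.10g")
                    artifacts[f"loocv_{m}_{ep}"] = p
                if (m, ep) in km_frames:
                    p = out / f"km_{m}_{ep}.csv"
                    km_frames[(m, ep)].to_csv(p, index=False, float_format="%.10g")
                    artifacts[f"km_{m}_{ep}"] = p

    log.info("pipeline complete (%.2fs)", time.perf_counter() - t_start)
    return AnalysisReport(
        config=config, cohort=df, report=_jsonify(report), artifacts=artifacts
    )


def _config_dict(config: AnalysisConfig, cohort_cfg: CohortConfig | None) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"] = cohort_cfg.to_dict() if cohort_cfg is not None else None
    return d
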