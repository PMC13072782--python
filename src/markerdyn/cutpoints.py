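"""Systematic threshold optimization for marker percentage changes.

Scans candidate cutoffs, fits a dichotomized Cox model at each (unfavorable
= change strictly above the cutoff), and selects the admissible cutoff with
minimal AIC.  Admissibility mirrors the selection criteria of data-driven
cutpoint studies: at least ``min_group`` patients in each stratum and a Wald
p below ``alpha``.  Two grid dialects are supported:

* ``"fixed"`` — a -50% to +50% grid in 5-point increments;
* ``"observed"`` (default) — every unique observed change inside the range,
  i.e. the maximally-selected profile, which can land between grid points.

A scan with no admissible candidate returns an undefined selection (not an
exception); the selection trace records each criterion's effect.

Note: no minimum-p multiplicity correction (maxstat-style) is applied to the
selected cutoff's p-value; the scan optimizes fit and therefore overstates
significance, which is why the bootstrap/LOOCV layer exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import as_cohort_frame
from .dynamics import endpoint_arrays, marker_pct_change
from .survival import _CoxData, _build_fit, _newton

__all__ = [
    "CutpointCandidate",
    "ThresholdScan",
    "GridSpec",
    "scan_thresholds",
    "select_cutoff",
    "stratify",
    "SelectedCutoff",
]

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"


@dataclass
class GridSpec:
    mode: str = "observed"  # or "fixed"
    lower: float = -50.0
    upper: float = 50.0
    step: float = 5.0

    def candidates(self, changes: np.ndarray) -> np.ndarray:
        if self.mode == "fixed":
            n_steps = int(round((self.upper - self.lower) / self.step))
            return self.lower + self.step * np.arange(n_steps + 1)
        if self.mode == "observed":
            u = np.unique(changes)
            return u[(u >= self.lower) & (u <= self.upper)]
        raise ValueError(f"unknown grid mode {self.mode!r}")


@dataclass
class CutpointCandidate:
    cutoff_pct: float
    hr: float
    hr_ci: tuple[float, float]
    p_value: float
    aic: float
    log_hr: float
    n_below: int
    n_above: int
    admissible: bool
    inadmissible_reason: str | None = None  # group_too_small | not_significant | fit_failed


@dataclass
class ThresholdScan:
    marker: str
    endpoint: str
    candidates: list[CutpointCandidate]
    selected_cutoff: float | None
    selection_trace: list[str]
    grid: GridSpec
    min_group: int
    alpha: float
    n: int

    def candidate_at(self, cutoff: float) -> CutpointCandidate | None:
        for c in self.candidates:
            if c.cutoff_pct == cutoff:
                return c
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff_pct": [c.cutoff_pct for c in self.candidates],
                "hr": [c.hr for c in self.candidates],
                "hr_lower95": [c.hr_ci[0] for c in self.candidates],
                "hr_upper95": [c.hr_ci[1] for c in self.candidates],
                "p_value": [c.p_value for c in self.candidates],
                "aic": [c.aic for c in self.candidates],
                "n_below": [c.n_below for c in self.candidates],
                "n_above": [c.n_above for c in self.candidates],
                "admissible": [c.admissible for c in self.candidates],
                "inadmissible_reason": [c.inadmissible_reason for c in self.candidates],
            }
        )


def _tie_break_order(cands: list[CutpointCandidate]) -> list[CutpointCandidate]:
    """Stable preference among equal-AIC candidates: larger |log HR|,
    then cutoff nearest 0."""
    return sorted(cands, key=lambda c: (-abs(c.log_hr), abs(c.cutoff_pct), c.cutoff_pct))


def scan_thresholds(
    records,
    marker: str,
    endpoint: str,
    grid: GridSpec | str | None = None,
    min_group: int = 10,
    alpha: float = 0.05,
) -> ThresholdScan:
    """Fit a dichotomized Cox model at every candidate cutoff.

    Invariant to the order of input records.  Candidates whose strata are
    smaller than ``min_group`` are still fitted (when both strata are
    non-empty) but marked inadmissible; non-convergent fits are marked
    ``fit_failed``.
    """
    df = as_cohort_frame(records)
    changes = marker_pct_change(df, marker)
    t, e = endpoint_arrays(df, endpoint)

    if grid is None:
        grid = GridSpec()
    elif isinstance(grid, str):
        grid = GridSpec(mode=grid)

    # canonical order so the scan ignores input record permutation
    order = np.argsort(t, kind="stable")
    t, e, changes = t[order], e[order], changes[order]

    data = _CoxData(t, e)
    cuts = grid.candidates(changes)
    n = t.size
    candidates: list[CutpointCandidate] = []
    for c in cuts:
        above = changes > c
        n_above = int(above.sum())
        n_below = n - n_above
        groups_ok = n_below >= min_group and n_above >= min_group
        if n_above == 0 or n_below == 0:
            candidates.append(
                CutpointCandidate(
                    float(c), float("nan"), (float("nan"), float("nan")),
                    float("nan"), float("nan"), float("nan"),
                    n_below, n_above, False, "group_too_small",
                )
            )
            continue
        x = above.astype(float)[data.order][:, None]
        beta, cov, ll, ll0, converged, msg = _newton(data, x)
        fit = _build_fit(["above_cutoff"], beta, cov, ll, ll0, n, data.n_events, converged, msg)
        if not converged:
            reason = "fit_failed"
            admissible = False
        elif not groups_ok:
            reason = "group_too_small"
            admissible = False
        elif not fit.p_values[0] < alpha:
            reason = "not_significant"
            admissible = False
        else:
            reason = None
            admissible = True
        candidates.append(
            CutpointCandidate(
                cutoff_pct=float(c),
                hr=float(fit.hazard_ratios[0]),
                hr_ci=(float(fit.hr_ci[0, 0]), float(fit.hr_ci[0, 1])),
                p_value=float(fit.p_values[0]),
                aic=float(fit.aic),
                log_hr=float(fit.coefficients[0]),
                n_below=n_below,
                n_above=n_above,
                admissible=admissible,
                inadmissible_reason=reason,
            )
        )

    trace = [
        f"grid={grid.mode}: {len(candidates)} candidate cutoffs in [{grid.lower}, {grid.upper}]",
        f"admissibility: n per stratum >= {min_group} and Wald p < {alpha}",
    ]
    admissible = [c for c in candidates if c.admissible]
    trace.append(f"{len(admissible)} admissible candidate(s)")
    if admissible:
        best_aic = min(c.aic for c in admissible)
        best = [c for c in admissible if c.aic == best_aic]
        chosen = _tie_break_order(best)[0]
        selected = chosen.cutoff_pct
        trace.append(f"minimum AIC {best_aic:.4f} at cutoff {selected:+.4g}%")
        if len(best) > 1:
            trace.append(
                "AIC tie broken by larger |log HR|, then cutoff nearest 0 "
                f"among {[c.cutoff_pct for c in best]}"
            )
    else:
        selected = None
        trace.append("no admissible candidate: selection undefined")

    return ThresholdScan(
        marker=marker,
        endpoint=endpoint,
        candidates=candidates,
        selected_cutoff=selected,
        selection_trace=trace,
        grid=grid,
        min_group=min_group,
        alpha=alpha,
        n=n,
    )


@dataclass
class SelectedCutoff:
    marker: str
    cutoff: float | None
    trace: list[str] = field(default_factory=list)


def select_cutoff(
    scan_pfs: ThresholdScan,
    scan_os: ThresholdScan,
    policy: str = "aic-rank-sum",
) -> SelectedCutoff:
    """Combine PFS and OS scans into one cutoff per marker.

    Default policy: over cutoffs admissible for PFS whose OS fit converged
    with adequate strata (OS significance not required), minimize the sum of
    the two scans' AIC ranks; ties broken by larger |log HR| on PFS, then by
    the cutoff nearest 0.
    """
    if scan_pfs.marker != scan_os.marker:
        raise ValueError("scans must concern the same marker")
    if policy != "aic-rank-sum":
        raise ValueError(f"unknown policy {policy!r}")
    marker = scan_pfs.marker
    trace: list[str] = [f"policy={policy}"]

    os_by_cut = {c.cutoff_pct: c for c in scan_os.candidates}
    joint: list[tuple[CutpointCandidate, CutpointCandidate]] = []
    for cp in scan_pfs.candidates:
        co = os_by_cut.get(cp.cutoff_pct)
        if co is None:
            continue
        os_ok = (
            co.inadmissible_reason != "fit_failed"
            and np.isfinite(co.aic)
            and co.n_below >= scan_os.min_group
            and co.n_above >= scan_os.min_group
        )
        if cp.admissible and os_ok:
            joint.append((cp, co))
    trace.append(f"{len(joint)} jointly eligible cutoff(s) (PFS admissible, OS fit usable)")
    if not joint:
        trace.append("selection undefined")
        return SelectedCutoff(marker=marker, cutoff=None, trace=trace)

    pfs_aics = np.array([cp.aic for cp, _ in joint])
    os_aics = np.array([co.aic for _, co in joint])
    from scipy.stats import rankdata

    ranks = rankdata(pfs_aics, method="average") + rankdata(os_aics, method="average")
    best_rank = ranks.min()
    tied = [joint[i][0] for i in np.flatnonzero(ranks == best_rank)]
    chosen = _tie_break_order(tied)[0]
    trace.append(f"minimum AIC rank sum {best_rank:.1f} at cutoff {chosen.cutoff_pct:+.4g}%")
    if len(tied) > 1:
        trace.append(
            f"rank tie among {[c.cutoff_pct for c in tied]} broken by |log HR| then |cutoff|"
        )
    return SelectedCutoff(marker=marker, cutoff=float(chosen.cutoff_pct), trace=trace)


def stratify(records, marker: str, cutoff: float):
    """Label patients favorable (change <= cutoff) / unfavorable (> cutoff).

    Returns (labels, excluded_ids): a pandas Series indexed by patient_id
    and the ids of records with missing marker values, which are excluded.
    """
    if cutoff is None or not np.isfinite(cutoff):
        raise ValueError("cutoff must be a defined finite value")
    from .cohort import MARKER_COLUMNS, cohort_to_frame

    # lenient on marker values: rows with missing markers are excluded and
    # reported rather than rejected outright
    df = records.copy() if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    b_col, p_col = MARKER_COLUMNS[marker]
    valid = df[b_col].notna() & df[p_col].notna() & (df[b_col] > 0) & (df[p_col] > 0)
    excluded = df.loc[~valid, "patient_id"].tolist()
    sub = df[valid]
    changes = (sub[p_col].to_numpy() - sub[b_col].to_numpy()) / sub[b_col].to_numpy() * 100.0
    labels = np.where(changes > cutoff, UNFAVORABLE, FAVORABLE)
    return pd.Series(labels, index=sub["patient_id"].to_numpy(), name="stratum"), excluded
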