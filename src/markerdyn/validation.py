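"""Internal validation of data-driven cutoffs: bootstrap re-optimization and
leave-one-out cross-validated classification concordance.

Data-driven thresholds are notoriously unstable at clinical sample sizes;
these two procedures quantify that instability.  The bootstrap repeats the
entire threshold-optimization procedure in resamples drawn with replacement
and summarizes the resulting cutoff distribution (proportion within a +/-5
percentage-point window of the original, percentile CI, quartiles).  LOOCV
re-derives the cutoff without each patient in turn and asks whether the
held-out patient's favorable/unfavorable label survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import as_cohort_frame
from .cutpoints import GridSpec, scan_thresholds
from .dynamics import marker_pct_change

__all__ = [
    "BootstrapStability",
    "LoocvResult",
    "bootstrap_stability",
    "loocv_concordance",
]


@dataclass
class BootstrapStability:
    marker: str
    endpoint: str
    original_cutoff: float
    n_iterations: int
    cutoffs: np.ndarray  # one per successful iteration
    n_failed: int
    window_halfwidth: float
    prop_within_window: float  # NaN when no iteration succeeded
    median: float
    mean: float
    iqr: tuple[float, float]
    ci95: tuple[float, float]
    seed: int


@dataclass
class LoocvResult:
    marker: str
    endpoint: str
    original_cutoff: float
    per_patient: pd.DataFrame  # patient_id, training_cutoff, predicted, original
    concordance_pct: float  # over classifiable patients; NaN if none
    n_unclassifiable: int


def _scan_cutoff(df, marker, endpoint, grid, min_group, alpha):
    scan = scan_thresholds(df, marker, endpoint, grid=grid, min_group=min_group, alpha=alpha)
    return scan.selected_cutoff


def bootstrap_stability(
    records,
    marker: str,
    endpoint: str,
    grid: GridSpec | str | None = None,
    min_group: int = 10,
    alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    window_halfwidth: float = 5.0,
    resample_indices=None,
) -> BootstrapStability:
    """Nonparametric bootstrap of the full cutoff-optimization procedure.

    Resampling indexes a canonical ordering by patient_id, so input record
    order does not affect the result.  Iterations whose resample yields no
    admissible cutoff are counted in ``n_failed`` and excluded from the
    summaries (reported, never imputed).  ``resample_indices`` (an iterable
    of index arrays) overrides the random resampling — used to pin down
    degenerate cases such as the identity resample.
    """
    df = as_cohort_frame(records).sort_values("patient_id", kind="stable").reset_index(drop=True)
    original = _scan_cutoff(df, marker, endpoint, grid, min_group, alpha)
    if original is None:
        raise ValueError("original selected cutoff is undefined; nothing to validate")

    n = len(df)
    if resample_indices is None:
        rng = np.random.default_rng(seed)
        index_iter = (rng.integers(0, n, size=n) for _ in range(n_iter))
        n_iterations = n_iter
    else:
        resample_indices = [np.asarray(ix) for ix in resample_indices]
        index_iter = iter(resample_indices)
        n_iterations = len(resample_indices)

    cutoffs: list[float] = []
    n_failed = 0
    for idx in index_iter:
        boot = df.iloc[idx].reset_index(drop=True)
        cut = _scan_cutoff(boot, marker, endpoint, grid, min_group, alpha)
        if cut is None:
            n_failed += 1
        else:
            cutoffs.append(cut)

    arr = np.asarray(cutoffs, dtype=float)
    if arr.size:
        prop = float(np.mean(np.abs(arr - original) <= window_halfwidth))
        med = float(np.median(arr))
        mean = float(np.mean(arr))
        q1, q3 = (float(v) for v in np.percentile(arr, [25, 75]))
        lo, hi = (float(v) for v in np.percentile(arr, [2.5, 97.5]))
    else:
        prop = med = mean = q1 = q3 = lo = hi = float("nan")

    return BootstrapStability(
        marker=marker,
        endpoint=endpoint,
        original_cutoff=float(original),
        n_iterations=n_iterations,
        cutoffs=arr,
        n_failed=n_failed,
        window_halfwidth=float(window_halfwidth),
        prop_within_window=prop,
        median=med,
        mean=mean,
        iqr=(q1, q3),
        ci95=(lo, hi),
        seed=seed,
    )


def loocv_concordance(
    records,
    marker: str,
    endpoint: str,
    grid: GridSpec | str | None = None,
    min_group: int = 10,
    alpha: float = 0.05,
) -> LoocvResult:
    """Leave-one-out cross-validated classification concordance.

    For each patient the cutoff is re-derived on the remaining n-1 records
    and the held-out patient classified by it; concordance is the percentage
    of classifiable patients whose LOOCV class matches their class under the
    original full-sample cutoff.  Folds with no admissible cutoff leave
    their patient unclassifiable (excluded from the percentage, counted).
    """
    df = as_cohort_frame(records).sort_values("patient_id", kind="stable").reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("LOOCV requires at least 3 patients")
    original = _scan_cutoff(df, marker, endpoint, grid, min_group, alpha)
    if original is None:
        raise ValueError("original selected cutoff is undefined; nothing to validate")

    changes = marker_pct_change(df, marker)
    original_class = np.where(changes > original, "unfavorable", "favorable")

    rows = []
    n_unclassifiable = 0
    n_concordant = 0
    n_classifiable = 0
    for i in range(len(df)):
        train = df.drop(index=i).reset_index(drop=True)
        cut = _scan_cutoff(train, marker, endpoint, grid, min_group, alpha)
        if cut is None:
            n_unclassifiable += 1
            predicted = None
        else:
            predicted = "unfavorable" if changes[i] > cut else "favorable"
            n_classifiable += 1
            if predicted == original_class[i]:
                n_concordant += 1
        rows.append(
            {
                "patient_id": df.loc[i, "patient_id"],
                "training_cutoff": cut,
                "predicted_class": predicted,
                "original_class": original_class[i],
            }
        )

    concordance = 100.0 * n_concordant / n_classifiable if n_classifiable else float("nan")
    return LoocvResult(
        marker=marker,
        endpoint=endpoint,
        original_cutoff=float(original),
        per_patient=pd.DataFrame(rows),
        concordance_pct=concordance,
        n_unclassifiable=n_unclassifiable,
    )
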