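"""Core survival statistics: Kaplan-Meier, log-rank, and Cox proportional hazards.

The Cox fitter maximizes the Efron-tie-corrected partial likelihood with a
Newton-Raphson iteration (step-halving, tolerance 1e-8 on the parameter step).
It is implemented in vectorized NumPy because the cutpoint-scanning and
resampling layers above it refit thousands of single-covariate models per
analysis; the per-fit cost must stay in the sub-millisecond range.

Conventions
-----------
* Subjects censored exactly at an event time remain in the risk set for that
  event time.
* Per-covariate inference is Wald-based (normal approximation on the
  log-hazard scale), matching the HR (95% CI) reporting style of clinical
  survival tables.
* ``aic = -2 * log_partial_likelihood + 2 * n_covariates`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "PHTestResult",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "schoenfeld_ph_test",
]

_Z975 = float(stats.norm.ppf(0.975))

# maximum |beta| before the likelihood is declared monotone (separation)
_BETA_DIVERGENCE = 25.0


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    ``event_times``/``survival``/``variance`` are aligned step-function arrays
    over the distinct event (not censoring) times.  ``median`` is the smallest
    time at which the estimate drops to 0.5 or below (``None`` if it never
    does); its CI inverts the log-log transformed pointwise bands
    (Brookmeyer-Crowley style).
    """

    event_times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    risk_table: dict[float, tuple[int, int]]
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function lookup S(t)."""
        idx = int(np.searchsorted(self.event_times, t, side="right")) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int
    groups: list
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron partial likelihood)."""

    covariate_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    hazard_ratios: np.ndarray
    hr_ci: np.ndarray  # (p, 2) lower/upper
    p_values: np.ndarray
    log_partial_likelihood: float
    null_log_partial_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool
    message: str = "converged"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "hr": self.hazard_ratios,
                "hr_lower95": self.hr_ci[:, 0],
                "hr_upper95": self.hr_ci[:, 1],
                "p": self.p_values,
            },
            index=self.covariate_names,
        )


@dataclass
class PHTestResult:
    """Scaled-Schoenfeld proportional-hazards diagnostic (per covariate)."""

    p_values: dict[str, float]
    defined: bool
    message: str = ""


# ---------------------------------------------------------------------------
# input validation helpers
# ---------------------------------------------------------------------------


def _as_surv_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-d array")
    if e.shape != t.shape:
        raise ValueError("times and events must have equal length")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be finite and strictly positive")
    eu = np.unique(e)
    if not np.all(np.isin(eu, [0, 1])):
        raise ValueError("events must be binary 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_fit(
    times,
    events,
    risk_table_timepoints: Sequence[float] | None = None,
) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    An all-censored input yields a curve identically 1 with undefined median
    (not an error).  The Greenwood variance term at a time where the risk set
    is exhausted (S drops to 0) is set to 0 by convention.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    t, e = _as_surv_arrays(times, events)

    kmf = KaplanMeierFitter()
    kmf.fit(t, e)

    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    d = ev["observed"].to_numpy(dtype=float)
    n_at = ev["at_risk"].to_numpy(dtype=float)

    # product-limit values at the event times, from the fitted step function
    surv = kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy()

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_j<=t} d_j / (n_j (n_j - d_j))
    with np.errstate(divide="ignore"):
        terms = np.where(n_at > d, d / (n_at * (n_at - d)), np.inf)
    var = surv**2 * np.cumsum(terms)
    var = np.where(surv == 0.0, 0.0, var)

    median = float(kmf.median_survival_time_)
    median_out: float | None = None if np.isinf(median) else median

    mci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(mci.iloc[0, 0]), float(mci.iloc[0, 1])
    median_ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)

    risk_table: dict[float, tuple[int, int]] = {}
    if risk_table_timepoints is not None:
        for tp in risk_table_timepoints:
            n_risk = int(np.sum(t >= tp))
            n_ev = int(np.sum(e[t <= tp]))
            risk_table[float(tp)] = (n_risk, n_ev)

    return KMCurve(
        event_times=event_times,
        survival=np.asarray(surv, dtype=float),
        variance=np.asarray(var, dtype=float),
        median=median_out,
        median_ci=median_ci,
        risk_table=risk_table,
        n=int(t.size),
        n_events=int(e.sum()),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def logrank_test(times, events, group_labels) -> LogRankResult:
    """Unweighted log-rank test over two or more groups.

    Observed and expected event counts per group are accumulated over the
    distinct event times with the hypergeometric variance; the chi-square
    statistic uses the first k-1 groups' covariance block.
    """
    t, e = _as_surv_arrays(times, events)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("group_labels must match times in length")
    groups = sorted(pd.unique(g).tolist())
    k = len(groups)
    if k < 2:
        raise ValueError("logrank_test requires at least 2 non-empty groups")
    lut = {lab: i for i, lab in enumerate(groups)}
    gi = np.array([lut[x] for x in g])

    event_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        dying = (t == et) & (e == 1)
        d = dying.sum()
        n_g = np.bincount(gi[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gi[dying], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            p = n_g / n
            V += (d * (n - d) / (n - 1)) * (np.diag(p) - np.outer(p, p))

    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    p_value = float(stats.chi2.sf(stat, df))
    return LogRankResult(
        statistic=stat, p_value=p_value, df=df, groups=groups, observed=O, expected=E
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


class _CoxData:
    """Covariate-independent precomputation for repeated Cox fits.

    Sorting, death grouping, and the Efron within-tie fractions depend only on
    (times, events); the cutpoint scanner reuses one instance across hundreds
    of candidate dichotomizations.
    """

    def __init__(self, times, events):
        t, e = _as_surv_arrays(times, events)
        if e.sum() == 0:
            raise ValueError("cox_fit requires at least one event")
        order = np.argsort(t, kind="stable")
        self.order = order
        self.t = t[order]
        self.e = e[order]
        self.n = t.size
        self.dmask = self.e == 1
        dt = self.t[self.dmask]
        u, counts = np.unique(dt, return_counts=True)
        self.n_events = int(dt.size)
        # first sorted index with time >= each unique event time
        grp_pos = np.searchsorted(self.t, u, side="left")
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        self.reduce_starts = starts
        self.pos_per_death = np.repeat(grp_pos, counts)
        d_per_death = np.repeat(counts, counts).astype(float)
        ranks = np.arange(self.n_events) - np.repeat(starts, counts)
        self.frac = ranks / d_per_death

    def loglik(self, X_sorted: np.ndarray, beta: np.ndarray) -> float:
        return self._eval(X_sorted, beta, order=0)[0]

    def _eval(self, X: np.ndarray, beta: np.ndarray, order: int = 2):
        eta = X @ beta
        c = float(eta.max())
        w = np.exp(eta - c)
        dmask = self.dmask
        pos = self.pos_per_death
        frac = self.frac
        starts = self.reduce_starts

        rc0 = np.cumsum(w[::-1])[::-1]
        wd = w[dmask]
        SD0 = np.repeat(np.add.reduceat(wd, starts), np.diff(np.append(starts, wd.size)))
        phi = rc0[pos] - frac * SD0
        ll = float(eta[dmask].sum() - np.log(phi).sum() - self.n_events * c)
        if order == 0:
            return (ll,)

        Xd = X[dmask]
        reps = np.diff(np.append(starts, wd.size))
        wx = w[:, None] * X
        rc1 = np.cumsum(wx[::-1], axis=0)[::-1]
        SD1 = np.repeat(np.add.reduceat(wd[:, None] * Xd, starts, axis=0), reps, axis=0)
        a1 = rc1[pos] - frac[:, None] * SD1
        gvec = a1 / phi[:, None]
        U = Xd.sum(axis=0) - gvec.sum(axis=0)
        if order == 1:
            return ll, U

        wxx = wx[:, :, None] * X[:, None, :]
        rc2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        SD2 = np.repeat(
            np.add.reduceat(wd[:, None, None] * Xd[:, :, None] * Xd[:, None, :], starts, axis=0),
            reps,
            axis=0,
        )
        a2 = rc2[pos] - frac[:, None, None] * SD2
        info = (a2 / phi[:, None, None]).sum(axis=0) - gvec.T @ gvec
        return ll, U, info


def _newton(
    data: _CoxData,
    X_sorted: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, float, bool, str]:
    """Newton-Raphson with step-halving on the Efron partial likelihood.

    Returns (beta, covariance, loglik, null_loglik, converged, message).
    """
    p = X_sorted.shape[1]
    beta = np.zeros(p)
    ll0 = data.loglik(X_sorted, beta)
    ll, U, info = data._eval(X_sorted, beta)
    converged = False
    message = "converged"
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * max(1.0, float(np.trace(info)))
            step = np.linalg.solve(info + ridge * np.eye(p), U)
        if float(np.abs(step).max()) < tol:
            converged = True
            break
        factor = 1.0
        new_ll = data.loglik(X_sorted, beta + step)
        for _ in range(30):
            if new_ll >= ll - 1e-13:
                break
            factor *= 0.5
            new_ll = data.loglik(X_sorted, beta + factor * step)
        beta = beta + factor * step
        if float(np.abs(beta).max()) > _BETA_DIVERGENCE:
            message = "monotone partial likelihood (possible complete separation)"
            break
        ll, U, info = data._eval(X_sorted, beta)
    else:
        message = "maximum iterations reached"

    ll, U, info = data._eval(X_sorted, beta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
        if message == "converged":
            message = "singular information matrix"
    return beta, cov, ll, ll0, converged, message


def _build_fit(
    names: list[str],
    beta: np.ndarray,
    cov: np.ndarray,
    ll: float,
    ll0: float,
    n: int,
    n_events: int,
    converged: bool,
    message: str,
) -> CoxFit:
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        z = beta / se
        p_values = 2.0 * stats.norm.sf(np.abs(z))
        hr = np.exp(beta)
        ci = np.column_stack([np.exp(beta - _Z975 * se), np.exp(beta + _Z975 * se)])
    k = beta.size
    return CoxFit(
        covariate_names=names,
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        hazard_ratios=hr,
        hr_ci=ci,
        p_values=p_values,
        log_partial_likelihood=ll,
        null_log_partial_likelihood=ll0,
        aic=-2.0 * ll + 2.0 * k,
        n=n,
        n_events=n_events,
        converged=converged,
        message=message,
    )


def cox_fit(
    times,
    events,
    covariates,
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron tie handling).

    Parameters
    ----------
    times, events
        Positive follow-up times and 0/1 event indicators.
    covariates
        (n, p) array-like; a 1-d input is treated as a single covariate.
    names
        Optional covariate names (default x0, x1, ...).

    A monotone partial likelihood (complete separation) is reported via
    ``converged=False`` with an explanatory message rather than a silently
    divergent estimate.  Constant covariates and event-free inputs raise.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = np.asarray(times, dtype=float)
    if X.shape[0] != t.size:
        raise ValueError("covariates and times must have equal length")
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates must be finite (no missing values)")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate column {j} is constant")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if len(names) != X.shape[1]:
        raise ValueError("names must match the number of covariate columns")

    data = _CoxData(times, events)
    Xs = X[data.order]
    beta, cov, ll, ll0, converged, message = _newton(data, Xs, tol=tol, max_iter=max_iter)
    return _build_fit(names, beta, cov, ll, ll0, data.n, data.n_events, converged, message)


# ---------------------------------------------------------------------------
# proportional hazards diagnostic
# ---------------------------------------------------------------------------


def schoenfeld_ph_test(
    times,
    events,
    covariates,
    names: Sequence[str] | None = None,
    time_transform: str = "km",
) -> PHTestResult:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    Uses the KM time transform (the R ``cox.zph`` default).  With fewer than
    3 events the test is undefined and flagged rather than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    t, e = _as_surv_arrays(times, events)
    if int(e.sum()) < 3:
        return PHTestResult(
            p_values={nm: float("nan") for nm in names},
            defined=False,
            message="fewer than 3 events: PH test undefined",
        )

    df = pd.DataFrame(X, columns=names)
    df["time"] = t
    df["event"] = e
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
        res = proportional_hazard_test(cph, df, time_transform=time_transform)
    summ = res.summary
    p_col = summ["p"]
    p_values: dict[str, float] = {}
    for nm in names:
        val = p_col.loc[nm]
        # with multiple transforms the index is (covariate, transform)
        p_values[nm] = float(np.atleast_1d(np.asarray(val))[0])
    return PHTestResult(p_values=p_values, defined=True)
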