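"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (explicit loops over risk sets) kept
separate from the package code paths they check.
"""

from __future__ import annotations

import numpy as np


def efron_loglik(beta, times, events, X) -> float:
    """Efron-tie-corrected Cox partial log-likelihood by direct enumeration."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = X @ beta
    exps = np.exp(eta)
    ll = 0.0
    for et in np.unique(times[events == 1]):
        dying = (times == et) & (events == 1)
        at_risk = times >= et
        d = int(dying.sum())
        s_dying = exps[dying].sum()
        s_risk = exps[at_risk].sum()
        ll += float(eta[dying].sum())
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_dying)
    return float(ll)


def grid_maximize_beta(times, events, x, lo=-5.0, hi=5.0) -> float:
    """Maximize the single-covariate Efron partial likelihood on successively
    refined grids; final resolution well below 1e-7."""
    center, width = (lo + hi) / 2.0, (hi - lo) / 2.0
    for _ in range(4):
        grid = np.linspace(center - width, center + width, 2001)
        lls = [efron_loglik(b, times, events, x) for b in grid]
        center = float(grid[int(np.argmax(lls))])
        width = 4.0 * (grid[1] - grid[0])
    return center


def km_by_hand(times, events):
    """Product-limit estimate with Greenwood variance, by direct counting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s, out_v = [], [], []
    s = 1.0
    gw = 0.0
    for et in np.unique(times[events == 1]):
        n = int((times >= et).sum())
        d = int(((times == et) & (events == 1)).sum())
        s *= (n - d) / n
        gw += d / (n * (n - d)) if n > d else np.inf
        out_t.append(et)
        out_s.append(s)
        out_v.append(0.0 if s == 0.0 else s * s * gw)
    return np.array(out_t), np.array(out_s), np.array(out_v)


def mann_whitney_auc(score_pos, score_neg) -> float:
    """P(score_pos > score_neg) + 0.5 P(equal), by full pairwise comparison."""
    sp = np.asarray(score_pos, dtype=float)[:, None]
    sn = np.asarray(score_neg, dtype=float)[None, :]
    return float(np.mean((sp > sn) + 0.5 * (sp == sn)))
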