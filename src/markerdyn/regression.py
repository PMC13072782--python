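"""Univariable screening and multivariable Cox modeling.

Reproduces the structure of a clinical survival regression table: one
univariable Cox fit per variable (multi-level categoricals as indicator
contrasts against a declared reference), a p < ``enter_p`` screen, and a
multivariable model built either by backward elimination (blocks dropped at
joint Wald p >= ``stay_p``; forced variables never dropped) or as a
forced-full fit of all candidates with no elimination.  Both modes are
first-class: backward elimination is the textbook rule, while forced-full
is what published tables often actually show when non-significant markers
are retained for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import as_cohort_frame
from .dynamics import endpoint_arrays
from .survival import CoxFit, cox_fit

__all__ = [
    "Variable",
    "DEFAULT_VARIABLES",
    "RegressionRow",
    "RegressionTable",
    "NonConvergenceError",
    "univariable_screen",
    "multivariable_model",
]


class NonConvergenceError(RuntimeError):
    """A Cox fit failed to converge; the offending model is named."""


@dataclass(frozen=True)
class Variable:
    """A model variable: a numeric column or a categorical with a reference."""

    name: str
    column: str
    kind: str = "categorical"  # or "numeric"
    reference: str | None = None


def DEFAULT_VARIABLES() -> list[Variable]:
    """The standard clinical covariates of the emulated cohort."""
    return [
        Variable("sex", "sex", "categorical", reference="male"),
        Variable("ras_status", "ras_status", "categorical", reference="mutant"),
        Variable("sidedness", "sidedness", "categorical", reference="rectum"),
        Variable("treatment_line", "treatment_line", "categorical", reference="third"),
    ]


@dataclass
class RegressionRow:
    variable: str
    level: str  # "level vs reference", "Ref", or "" for numeric
    hr: float | None
    hr_ci: tuple[float, float] | None
    p_value: float | None
    is_reference: bool = False


@dataclass
class RegressionTable:
    endpoint: str
    rows: list[RegressionRow]
    inclusion_rule: dict
    mode: str  # "univariable", "backward", "forced-full"
    passed: list[str] = field(default_factory=list)  # screen survivors
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)
    eliminated: list[tuple[str, float]] = field(default_factory=list)  # (variable, p at drop)
    block_p: dict = field(default_factory=dict)
    fit: CoxFit | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [r.variable for r in self.rows],
                "level": [r.level for r in self.rows],
                "hr": [r.hr for r in self.rows],
                "hr_lower95": [r.hr_ci[0] if r.hr_ci else None for r in self.rows],
                "hr_upper95": [r.hr_ci[1] if r.hr_ci else None for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
            }
        )

    def to_text(self) -> str:
        lines = [f"{self.endpoint} Cox regression ({self.mode})"]
        for r in self.rows:
            if r.is_reference:
                lines.append(f"  {r.variable}: {r.level}  Ref")
            else:
                lines.append(
                    f"  {r.variable}: {r.level}  "
                    f"HR {r.hr:.2f} ({r.hr_ci[0]:.2f}-{r.hr_ci[1]:.2f}), p = {r.p_value:.3f}"
                )
        if self.eliminated:
            drops = ", ".join(f"{v} (p={p:.3f})" for v, p in self.eliminated)
            lines.append(f"  eliminated: {drops}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _variable_block(df: pd.DataFrame, var: Variable):
    """Indicator design block for one variable.

    Returns (X_block, column_labels, reference_label) or a string reason
    when the variable cannot enter (constant, missing reference level).
    """
    if var.column not in df.columns:
        return f"column {var.column!r} not in cohort"
    col = df[var.column]
    if var.kind == "numeric":
        x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            return "missing values"
        if np.ptp(x) == 0:
            return "constant"
        return x[:, None], [""], None
    levels = sorted(pd.unique(col.astype(str)).tolist())
    if len(levels) < 2:
        return "constant"
    ref = var.reference if var.reference is not None else levels[0]
    if ref not in levels:
        return f"reference level {ref!r} not observed"
    contrast_levels = [lv for lv in levels if lv != ref]
    X = np.column_stack([(col.astype(str) == lv).to_numpy(dtype=float) for lv in contrast_levels])
    labels = [f"{lv} vs {ref}" for lv in contrast_levels]
    return X, labels, ref


def _joint_wald_p(fit: CoxFit, idx: list[int]) -> float:
    beta = fit.coefficients[idx]
    sub = fit.covariance[np.ix_(idx, idx)]
    try:
        w = float(beta @ np.linalg.solve(sub, beta))
    except np.linalg.LinAlgError:
        return float("nan")
    return float(stats.chi2.sf(w, len(idx)))


def _fit_blocks(df, variables: list[Variable], endpoint: str):
    """Fit one Cox model containing all given variables as blocks."""
    t, e = endpoint_arrays(df, endpoint)
    parts, names, owners, refs = [], [], [], {}
    for var in variables:
        block = _variable_block(df, var)
        if isinstance(block, str):
            raise ValueError(f"variable {var.name!r} cannot enter the model: {block}")
        X, labels, ref = block
        parts.append(X)
        names.extend(f"{var.name}::{lab}" if lab else var.name for lab in labels)
        owners.extend([var.name] * X.shape[1])
        refs[var.name] = ref
    X = np.column_stack(parts)
    fit = cox_fit(t, e, X, names=names)
    block_idx = {
        v.name: [i for i, o in enumerate(owners) if o == v.name] for v in variables
    }
    return fit, block_idx, refs


def _rows_from_fit(fit: CoxFit, variables: list[Variable], block_idx, refs) -> list[RegressionRow]:
    rows: list[RegressionRow] = []
    for var in variables:
        ref = refs.get(var.name)
        if ref is not None:
            rows.append(RegressionRow(var.name, ref, None, None, None, is_reference=True))
        for i in block_idx[var.name]:
            label = fit.covariate_names[i].split("::", 1)[-1] if "::" in fit.covariate_names[i] else ""
            rows.append(
                RegressionRow(
                    variable=var.name,
                    level=label,
                    hr=float(fit.hazard_ratios[i]),
                    hr_ci=(float(fit.hr_ci[i, 0]), float(fit.hr_ci[i, 1])),
                    p_value=float(fit.p_values[i]),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def univariable_screen(
    records,
    variables: list[Variable],
    endpoint: str,
    enter_p: float = 0.10,
) -> RegressionTable:
    """One single-variable Cox fit per variable; flags p < ``enter_p``.

    Multi-level categoricals enter as one model with indicator contrasts and
    are screened on their joint Wald p.  Constant variables are excluded
    with a reason rather than raising.
    """
    df = as_cohort_frame(records)
    rows: list[RegressionRow] = []
    passed: list[str] = []
    excluded: list[tuple[str, str]] = []
    block_ps: dict[str, float] = {}
    for var in variables:
        block = _variable_block(df, var)
        if isinstance(block, str):
            excluded.append((var.name, block))
            continue
        fit, block_idx, refs = _fit_blocks(df, [var], endpoint)
        if not fit.converged:
            excluded.append((var.name, f"fit did not converge ({fit.message})"))
            continue
        idx = block_idx[var.name]
        p_block = _joint_wald_p(fit, idx) if len(idx) > 1 else float(fit.p_values[idx[0]])
        block_ps[var.name] = p_block
        if p_block < enter_p:
            passed.append(var.name)
        rows.extend(_rows_from_fit(fit, [var], block_idx, refs))
    return RegressionTable(
        endpoint=endpoint,
        rows=rows,
        inclusion_rule={"enter_p": enter_p},
        mode="univariable",
        passed=passed,
        excluded=excluded,
        block_p=block_ps,
    )


def multivariable_model(
    records,
    screened_variables: list[Variable],
    forced_variables: list[Variable] | None,
    endpoint: str,
    stay_p: float = 0.05,
    mode: str = "backward",
) -> RegressionTable:
    """Multivariable Cox model from screened + forced variables.

    ``mode="backward"``: iteratively drop the block with the largest joint
    Wald p >= ``stay_p`` (never a forced variable) and refit, until every
    remaining block is significant or forced.  Elimination is deterministic:
    p ties are broken by variable name order.  ``mode="forced-full"``: fit
    all candidates once, eliminate nothing.
    """
    if mode not in ("backward", "forced-full"):
        raise ValueError("mode must be 'backward' or 'forced-full'")
    forced_variables = forced_variables or []
    df = as_cohort_frame(records)

    current: list[Variable] = []
    seen = set()
    for var in list(screened_variables) + list(forced_variables):
        if var.name not in seen:
            current.append(var)
            seen.add(var.name)
    if not current:
        raise ValueError("no candidate variables for the multivariable model")
    forced_names = {v.name for v in forced_variables}

    n_events = int(endpoint_arrays(df, endpoint)[1].sum())
    if n_events < 5 * len(current):
        import warnings

        warnings.warn(
            f"{n_events} events for {len(current)} candidate variables "
            "(< 5 events per variable); estimates may be unstable",
            stacklevel=2,
        )

    eliminated: list[tuple[str, float]] = []
    while True:
        fit, block_idx, refs = _fit_blocks(df, current, endpoint)
        if not fit.converged:
            raise NonConvergenceError(
                f"{endpoint} model with variables "
                f"{[v.name for v in current]} did not converge: {fit.message}"
            )
        if mode == "forced-full":
            break
        block_ps = {
            v.name: (
                _joint_wald_p(fit, block_idx[v.name])
                if len(block_idx[v.name]) > 1
                else float(fit.p_values[block_idx[v.name][0]])
            )
            for v in current
        }
        droppable = sorted(
            (
                (p, name)
                for name, p in block_ps.items()
                if name not in forced_names and p >= stay_p
            ),
            key=lambda t: (-t[0], t[1]),
        )
        if not droppable or len(current) == 1:
            break
        worst_p, worst_name = droppable[0]
        eliminated.append((worst_name, worst_p))
        current = [v for v in current if v.name != worst_name]

    block_ps = {
        v.name: (
            _joint_wald_p(fit, block_idx[v.name])
            if len(block_idx[v.name]) > 1
            else float(fit.p_values[block_idx[v.name][0]])
        )
        for v in current
    }
    return RegressionTable(
        endpoint=endpoint,
        rows=_rows_from_fit(fit, current, block_idx, refs),
        inclusion_rule={"stay_p": stay_p, "forced": sorted(forced_names)},
        mode=mode,
        eliminated=eliminated,
        block_p=block_ps,
        fit=fit,
    )
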