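"""Slacks-based measure (SBM) DEA with undesirable outputs.

Eco-efficiency of a region-year is measured against the frontier spanned by
all decision-making units (DMUs) in the comparison set.  The non-oriented
SBM score of unit *o* with inputs x, desirable outputs y^g and undesirable
outputs y^b is

    rho = min  [1 - (1/m) sum_i s_i^- / x_io]
               / [1 + 1/(s1+s2) (sum_r s_r^g / y_ro^g + sum_r s_r^b / y_ro^b)]

subject to  x_o  = X lambda + s^-,
            y_o^g = Y^g lambda - s^g,
            y_o^b = Y^b lambda + s^b,   lambda, s >= 0,

with an optional convexity constraint sum(lambda) = 1 under variable
returns to scale.  The fractional program is linearized with the
Charnes-Cooper transform (multiply all variables by a scalar t that pins
the denominator to 1) and solved as a single linear program with HiGHS.
The score is 1 exactly when every slack is zero, i.e. the unit is on the
frontier; it is invariant to rescaling any input/output column across all
DMUs because every slack is normalized by the unit's own observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from ecohealth.panel import (
    DEA_BAD_COLUMNS,
    DEA_GOOD_COLUMNS,
    DEA_INPUT_COLUMNS,
    PanelDataset,
    REE_COLUMN,
)

#: slacks below this (relative) threshold are treated as zero when deciding rho = 1
SLACK_TOL = 1e-7


class DEAValidationError(ValueError):
    """Raised for nonpositive data or a missing unit."""


class DEASolverError(RuntimeError):
    """Raised when the linear program fails (signals a numerical problem)."""


@dataclass(frozen=True)
class DEAProblem:
    """Inputs and outputs of every DMU in one comparison set.

    All arrays are (n_units, k)-shaped; ``bad_outputs`` may have zero
    columns when there are no undesirable outputs.  All observed values
    must be strictly positive because the SBM objective divides by them.
    """

    units: tuple[str, ...]
    inputs: np.ndarray
    good_outputs: np.ndarray
    bad_outputs: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.units)
        if n < 1:
            raise DEAValidationError("at least one DMU is required")
        for name in ("inputs", "good_outputs", "bad_outputs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[0] != n:
                raise DEAValidationError(f"{name} must be 2-D with {n} rows")
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
                raise DEAValidationError(f"{name} must be strictly positive and finite")
            object.__setattr__(self, name, arr)
        if self.good_outputs.shape[1] < 1:
            raise DEAValidationError("at least one desirable output is required")
        if self.inputs.shape[1] < 1:
            raise DEAValidationError("at least one input is required")

    def index_of(self, unit: str) -> int:
        try:
            return self.units.index(unit)
        except ValueError:
            raise DEAValidationError(f"unit {unit!r} not in problem") from None


@dataclass(frozen=True)
class EfficiencyScore:
    """SBM efficiency of one DMU with its optimal slacks and frontier weights."""

    unit: str
    rho: float
    input_slacks: np.ndarray
    good_output_slacks: np.ndarray
    bad_output_slacks: np.ndarray
    lambdas: np.ndarray

    @property
    def is_efficient(self) -> bool:
        return bool(self.rho >= 1.0 - SLACK_TOL)


def sbm_efficiency(
    problem: DEAProblem, unit: str, returns_to_scale: str = "constant"
) -> EfficiencyScore:
    """Score one DMU by solving the linearized SBM program.

    Parameters
    ----------
    returns_to_scale:
        ``"constant"`` (default) or ``"variable"`` (adds the convexity
        constraint on the frontier weights).
    """
    if returns_to_scale not in ("constant", "variable"):
        raise DEAValidationError(
            f"returns_to_scale must be 'constant' or 'variable', got {returns_to_scale!r}"
        )
    o = problem.index_of(unit)
    X = problem.inputs
    Yg = problem.good_outputs
    Yb = problem.bad_outputs
    n, m = X.shape
    s1 = Yg.shape[1]
    s2 = Yb.shape[1]
    x0, yg0 = X[o], Yg[o]
    yb0 = Yb[o] if s2 else np.empty(0)

    # variables: [t, Lambda (n), S_in (m), S_good (s1), S_bad (s2)]
    nv = 1 + n + m + s1 + s2
    i_t = 0
    i_lam = slice(1, 1 + n)
    i_sin = slice(1 + n, 1 + n + m)
    i_sg = slice(1 + n + m, 1 + n + m + s1)
    i_sb = slice(1 + n + m + s1, nv)

    c = np.zeros(nv)
    c[i_t] = 1.0
    c[i_sin] = -1.0 / (m * x0)

    rows: list[np.ndarray] = []
    rhs: list[float] = []

    # denominator pinned to 1: t + (1/(s1+s2)) (sum S_g/yg0 + sum S_b/yb0) = 1
    row = np.zeros(nv)
    row[i_t] = 1.0
    row[i_sg] = 1.0 / ((s1 + s2) * yg0)
    if s2:
        row[i_sb] = 1.0 / ((s1 + s2) * yb0)
    rows.append(row)
    rhs.append(1.0)

    for i in range(m):  # X Lambda + S_in = t * x0
        row = np.zeros(nv)
        row[i_lam] = X[:, i]
        row[1 + n + i] = 1.0
        row[i_t] = -x0[i]
        rows.append(row)
        rhs.append(0.0)
    for r in range(s1):  # Yg Lambda - S_good = t * yg0
        row = np.zeros(nv)
        row[i_lam] = Yg[:, r]
        row[1 + n + m + r] = -1.0
        row[i_t] = -yg0[r]
        rows.append(row)
        rhs.append(0.0)
    for r in range(s2):  # Yb Lambda + S_bad = t * yb0
        row = np.zeros(nv)
        row[i_lam] = Yb[:, r]
        row[1 + n + m + s1 + r] = 1.0
        row[i_t] = -yb0[r]
        rows.append(row)
        rhs.append(0.0)
    if returns_to_scale == "variable":  # sum(lambda) = 1, scaled by t
        row = np.zeros(nv)
        row[i_lam] = 1.0
        row[i_t] = -1.0
        rows.append(row)
        rhs.append(0.0)

    bounds = [(1e-9, None)] + [(0.0, None)] * (nv - 1)
    res = linprog(c, A_eq=np.vstack(rows), b_eq=np.asarray(rhs), bounds=bounds, method="highs")
    if not res.success:
        raise DEASolverError(f"SBM LP failed for unit {unit!r}: {res.message}")

    t = res.x[i_t]
    rho = float(min(res.fun, 1.0))
    lambdas = res.x[i_lam] / t
    s_in = res.x[i_sin] / t
    s_g = res.x[i_sg] / t
    s_b = res.x[i_sb] / t
    # snap numerically-clean frontier units to exactly 1
    rel_slack = max(
        np.max(s_in / x0, initial=0.0),
        np.max(s_g / yg0, initial=0.0),
        np.max(s_b / yb0, initial=0.0) if s2 else 0.0,
    )
    if rel_slack < SLACK_TOL:
        rho = 1.0
        s_in = np.zeros_like(s_in)
        s_g = np.zeros_like(s_g)
        s_b = np.zeros_like(s_b)
    if not 0.0 < rho <= 1.0:
        raise DEASolverError(f"SBM score out of range for unit {unit!r}: rho={rho}")
    return EfficiencyScore(
        unit=unit, rho=rho, input_slacks=s_in, good_output_slacks=s_g,
        bad_output_slacks=s_b, lambdas=lambdas,
    )


def problem_from_frame(df: pd.DataFrame, unit_labels: list[str]) -> DEAProblem:
    """Build a :class:`DEAProblem` from panel rows using the standard DEA columns."""
    return DEAProblem(
        units=tuple(unit_labels),
        inputs=df[list(DEA_INPUT_COLUMNS)].to_numpy(dtype=float),
        good_outputs=df[list(DEA_GOOD_COLUMNS)].to_numpy(dtype=float),
        bad_outputs=df[list(DEA_BAD_COLUMNS)].to_numpy(dtype=float),
    )


def score_panel(
    panel: PanelDataset, per_year: bool = True, returns_to_scale: str = "constant"
) -> PanelDataset:
    """Fill the panel's ``ree`` column with SBM efficiency scores.

    With ``per_year=True`` (default) each calendar year forms its own
    cross-sectional frontier; otherwise all region-years are pooled into a
    single frontier.
    """
    df = panel.data
    ree = pd.Series(np.nan, index=df.index)
    if per_year:
        groups = [(str(y), sub) for y, sub in df.groupby("year")]
    else:
        groups = [("pooled", df)]
    for label, sub in groups:
        units = [f"{r}:{y}" for r, y in zip(sub["region"], sub["year"])]
        problem = problem_from_frame(sub, units)
        for idx, unit in zip(sub.index, units):
            try:
                score = sbm_efficiency(problem, unit, returns_to_scale)
            except (DEAValidationError, DEASolverError) as exc:
                raise DEASolverError(f"scoring failed in frontier {label!r}: {exc}") from exc
            ree.loc[idx] = score.rho
    return panel.with_ree(ree)
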