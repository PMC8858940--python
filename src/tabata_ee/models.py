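"""Variable screening and period-specific linear energy-expenditure models.

Covers Pearson-correlation ranking of the pre-selected predictor sets,
stepwise (forward-with-backward-elimination) linear regression at the
conventional p < 0.05 entry rule, and the fixed published regression
equations for the exercise and interval periods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

EXERCISE_CANDIDATES = [
    "vm_dominant_hand", "vm_nondominant_hand", "vm_right_hip",
    "vm_right_ankle", "hr_exercise",
    "height", "weight", "sex_code", "age", "bmi", "body_fat",
]

INTERVAL_CANDIDATES = [
    "vm_exe_0_10", "vm_exe_10_20", "vm_exe_0_20", "vm_stage",
    "hr_exe_0_10", "hr_exe_10_20", "hr_exe_0_20", "hr_stage", "hr_interval",
    "height", "weight", "sex_code", "age", "bmi", "body_fat",
]


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_table(design: pd.DataFrame, variables: Sequence[str],
                      period: str, target: str = "ee") -> pd.DataFrame:
    """Pearson r and p of each candidate variable against the EE target."""
    rows = []
    for name in variables:
        try:
            r, p = pearson(design[name], design[target])
        except ValueError:
            continue  # constant column carries no information
        rows.append({"variable": name, "r": r, "p": p, "period": period})
    return pd.DataFrame(rows)


def rank_variables(table: pd.DataFrame) -> list[str]:
    """Variables in descending |r| order; ties broken alphabetically."""
    if len(table) == 0:
        raise ValueError("empty correlation table")
    ordered = table.assign(abs_r=table["r"].abs()).sort_values(
        ["abs_r", "variable"], ascending=[False, True])
    return list(ordered["variable"])


# ---------------------------------------------------------------------------
# linear model specs
# ---------------------------------------------------------------------------

@dataclass
class LinearModelSpec:
    """A fitted or published linear EE predictor for one period."""

    period: str
    intercept: float
    terms: list[tuple[str, float, float | None]]  # (name, coef, p-value)
    r_squared: float | None = None
    intercept_only: bool = False
    notes: str = ""

    @property
    def variables(self) -> list[str]:
        return [name for name, _, _ in self.terms]

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        """Evaluate the linear combination on a design frame (kcal/window)."""
        out = np.full(len(design), self.intercept, dtype=float)
        for name, coef, _ in self.terms:
            out += coef * design[name].to_numpy(dtype=float)
        return out

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "intercept": self.intercept,
            "terms": [list(t) for t in self.terms],
            "r_squared": self.r_squared,
            "intercept_only": self.intercept_only,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModelSpec":
        return cls(period=d["period"], intercept=d["intercept"],
                   terms=[tuple(t) for t in d["terms"]],
                   r_squared=d.get("r_squared"),
                   intercept_only=d.get("intercept_only", False),
                   notes=d.get("notes", ""))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "LinearModelSpec":
        return cls.from_dict(json.loads(s))


#: published exercise-period equation:
#: EE = 0.000044*VM_ankle(10 s) + 0.193*HR_exe + 0.23*BW - 3.05, r^2 0.71
PUBLISHED_EXERCISE = LinearModelSpec(
    period="exercise", intercept=-3.05,
    terms=[("vm_right_ankle", 0.000044, None),
           ("hr_exercise", 0.193, None),
           ("weight", 0.23, None)],
    r_squared=0.71,
    notes="published coefficients, used exactly as printed",
)

#: published interval-period equation:
#: EE = 0.000011*VM_stage(30 s) + 0.0116*HR_exe(0-10 s) + 0.030*BW - 1.99
PUBLISHED_INTERVAL = LinearModelSpec(
    period="interval", intercept=-1.99,
    terms=[("vm_stage", 0.000011, None),
           ("hr_exe_0_10", 0.0116, None),
           ("weight", 0.030, None)],
    r_squared=0.73,
    notes="published coefficients, used exactly as printed",
)


def predict_published_exercise(vm_exercise: float, hr_exercise: float,
                               weight: float) -> float:
    """Published exercise equation evaluated at one window (kcal/10 s)."""
    return (0.000044 * vm_exercise + 0.193 * hr_exercise
            + 0.23 * weight - 3.05)


def predict_published_interval(vm_stage: float, hr_exercise_0_10: float,
                               weight: float) -> float:
    """Published interval equation evaluated at one stage (kcal/10 s)."""
    return (0.000011 * vm_stage + 0.0116 * hr_exercise_0_10
            + 0.030 * weight - 1.99)


# ---------------------------------------------------------------------------
# stepwise fitting
# ---------------------------------------------------------------------------

def _ols(X: pd.DataFrame, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits emit divide warnings
        return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _term_pvalues(fit, names: list[str]) -> dict[str, float]:
    p = fit.pvalues
    out = {}
    for name in names:
        v = float(p[name])
        if np.isnan(v):
            # 0/0 t-statistic: a coefficient that is exactly zero in a
            # perfect fit carries no evidence -> treat as insignificant
            v = 1.0 if abs(float(fit.params[name])) < 1e-12 else 0.0
        out[name] = v
    return out


def stepwise_fit(design: pd.DataFrame, target: Sequence[float] | str = "ee",
                 candidates: Sequence[str] | None = None,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 period: str = "") -> LinearModelSpec:
    """Forward stepwise regression with backward elimination.

    Repeatedly adds the candidate whose partial-test p-value is smallest and
    below ``p_enter``, then drops any included term whose p-value exceeds
    ``p_remove``.  Returns the fitted coefficients, per-term p-values and
    r-squared; if no candidate is ever admissible the intercept-only model is
    returned with ``intercept_only=True``.
    """
    if isinstance(target, str):
        y = design[target].to_numpy(dtype=float)
    else:
        y = np.asarray(target, dtype=float)
    if candidates is None:
        candidates = [c for c in design.columns if c != "ee"
                      and np.issubdtype(design[c].dtype, np.number)]
    candidates = [c for c in candidates if c in design.columns]
    if len(design) < 10 * len(candidates):
        warnings.warn(
            f"only {len(design)} rows for {len(candidates)} candidates; "
            "stepwise selection may be unstable", stacklevel=2)

    ss_tot = float(((y - y.mean()) ** 2).sum())
    included: list[str] = []
    seen_states: set[frozenset] = set()
    while True:
        if included:
            # a numerically perfect fit leaves only roundoff residuals, on
            # which further partial tests are meaningless
            ssr = float(_ols(design[included], y).ssr)
            if ssr <= 1e-12 * max(ss_tot, 1e-300):
                break
        # forward step: best admissible candidate
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in included:
                continue
            x = design[name].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            if included:
                # skip candidates with no variation beyond the current design
                Z = sm.add_constant(design[included], has_constant="add")
                resid = x - Z.to_numpy() @ np.linalg.lstsq(
                    Z.to_numpy(), x, rcond=None)[0]
                if np.var(resid) <= 1e-12 * max(np.var(x), 1.0):
                    continue
            fit = _ols(design[included + [name]], y)
            p = _term_pvalues(fit, [name])[name]
            if p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= p_enter:
            break
        included.append(best_name)
        # backward step: drop terms that lost significance
        while included:
            fit = _ols(design[included], y)
            pvals = _term_pvalues(fit, included)
            worst = max(included, key=lambda n: pvals[n])
            if pvals[worst] > p_remove:
                included.remove(worst)
            else:
                break
        state = frozenset(included)
        if state in seen_states:
            break  # add/remove cycle: stop at the repeated state
        seen_states.add(state)

    if not included:
        return LinearModelSpec(period=period, intercept=float(np.mean(y)),
                               terms=[], r_squared=0.0, intercept_only=True,
                               notes="no candidate reached p_enter")
    fit = _ols(design[included], y)
    pvals = _term_pvalues(fit, included)
    return LinearModelSpec(
        period=period,
        intercept=float(fit.params["const"]),
        terms=[(n, float(fit.params[n]), pvals[n]) for n in included],
        r_squared=float(fit.rsquared),
    )


def stepwise_standard_errors(design: pd.DataFrame, spec: LinearModelSpec,
                             target: str = "ee") -> dict[str, float]:
    """OLS standard errors of the selected terms (refit on the same design)."""
    fit = _ols(design[spec.variables],
               design[target].to_numpy(dtype=float))
    return {n: float(fit.bse[n]) for n in spec.variables}


def r_squared(measured: Sequence[float], fitted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    m = np.asarray(measured, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if m.shape != f.shape or m.ndim != 1 or len(m) < 2:
        raise ValueError("need equal-length vectors of at least 2 values")
    ss_tot = float(((m - m.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero total variance: r^2 undefined")
    ss_res = float(((m - f) ** 2).sum())
    return 1.0 - ss_res / ss_tot
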