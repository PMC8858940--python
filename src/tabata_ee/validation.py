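"""Agreement validation of EE predictors.

Subject-level train/test partitioning, MAPE/RMSE error metrics, Bland-Altman
limits-of-agreement analysis, per-stage error decomposition and the combined
comparative report for the linear-regression and neural-network models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MEASURED_DENOMINATOR = "measured-denominator"
AS_PRINTED = "as-printed"  # predicted value in the denominator


def split_subjects(subject_ids: Sequence[str], ratio_train: float = 0.75,
                   seed: int = 0, n_test: int | None = None
                   ) -> tuple[list[str], list[str]]:
    """Seeded subject-level random partition into train and test ids.

    Train size is round-half-up of ``ratio_train * n`` (so 45 subjects at
    3:1 give 34/11), clamped to leave at least one subject per side.  An
    explicit ``n_test`` overrides the ratio (e.g. a 15-subject validation
    group out of 45).
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    if n_test is not None:
        if not 1 <= n_test <= n - 1:
            raise ValueError("n_test must leave at least one training subject")
        n_train = n - n_test
    else:
        if not 0.0 < ratio_train < 1.0:
            raise ValueError("ratio_train must lie strictly in (0, 1)")
        n_train = int(np.floor(ratio_train * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


def mape(measured: Sequence[float], predicted: Sequence[float],
         convention: str = MEASURED_DENOMINATOR) -> float:
    """Mean absolute percentage error, in percent.

    The default convention divides by the measured value; the "as-printed"
    convention divides by the predicted value instead.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or len(m) == 0:
        raise ValueError("need equal-length nonempty vectors")
    denom = m if convention == MEASURED_DENOMINATOR else p
    if convention not in (MEASURED_DENOMINATOR, AS_PRINTED):
        raise ValueError(f"unknown MAPE convention {convention!r}")
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        raise ValueError(f"zero denominator at index {int(zero[0])}")
    return float(100.0 * np.mean(np.abs(m - p) / np.abs(denom)))


def rmse(measured: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error (kcal)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or len(m) == 0:
        raise ValueError("need equal-length nonempty vectors")
    return float(np.sqrt(np.mean((m - p) ** 2)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Limits-of-agreement summary of measured-vs-predicted differences."""

    mean_diff: float  # kcal
    sd_diff: float  # kcal, sample SD (n-1)
    loa_low: float  # mean - 1.96 SD
    loa_high: float  # mean + 1.96 SD
    pct_within: float  # % of points inside [loa_low, loa_high] (inclusive)
    n_points: int

    def to_dict(self) -> dict:
        return dict(mean_diff=self.mean_diff, sd_diff=self.sd_diff,
                    loa_low=self.loa_low, loa_high=self.loa_high,
                    pct_within=self.pct_within, n_points=self.n_points)


def bland_altman(measured: Sequence[float],
                 predicted: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of measured minus predicted.

    Limits are mean difference +/- 1.96 sample SD; points exactly on a limit
    count as within.  The conventional x-coordinate (pairwise mean) is
    returned by :func:`bland_altman_points` for plotting.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or len(m) < 2:
        raise ValueError("need equal-length vectors of at least 2 points")
    d = m - p
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd, loa_low=lo,
                             loa_high=hi, pct_within=within, n_points=len(d))


def bland_altman_points(measured: Sequence[float],
                        predicted: Sequence[float]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(pairwise mean, difference) coordinates for a Bland-Altman plot."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    return (m + p) / 2.0, m - p


def per_stage_mape(measured: Sequence[float], predicted: Sequence[float],
                   stage_index: Sequence[int], n_stages: int,
                   convention: str = MEASURED_DENOMINATOR,
                   threshold: float = 15.0
                   ) -> tuple[np.ndarray, int]:
    """MAPE restricted to each stage's windows, plus the count of stages
    whose MAPE exceeds the threshold (default 15%)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    s = np.asarray(stage_index, dtype=int)
    out = np.empty(n_stages)
    for k in range(n_stages):
        sel = s == k
        if not sel.any():
            raise ValueError(f"no windows for stage {k}")
        out[k] = mape(m[sel], p[sel], convention)
    return out, int(np.sum(out > threshold))


@dataclass
class ModelPeriodMetrics:
    mape: float
    mape_se: float
    rmse: float
    bland_altman: BlandAltmanResult
    n_points: int

    def to_dict(self) -> dict:
        return dict(mape=self.mape, mape_se=self.mape_se, rmse=self.rmse,
                    bland_altman=self.bland_altman.to_dict(),
                    n_points=self.n_points)


@dataclass
class ValidationReport:
    """All agreement metrics, per model and period plus overall."""

    convention: str
    n_test_subjects: int
    n_stages: int
    per_period: dict  # model -> period -> ModelPeriodMetrics
    overall: dict  # model -> {mape, mape_se, rmse, bland_altman, n_points}
    stage_mape: dict  # model -> list of n_stages MAPEs
    stages_above_15: dict  # model -> count

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "n_test_subjects": self.n_test_subjects,
            "n_stages": self.n_stages,
            "per_period": {
                mdl: {per: met.to_dict() for per, met in d.items()}
                for mdl, d in self.per_period.items()},
            "overall": {mdl: met.to_dict()
                        for mdl, met in self.overall.items()},
            "stage_mape": {mdl: list(map(float, v))
                           for mdl, v in self.stage_mape.items()},
            "stages_above_15": dict(self.stages_above_15),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        def metrics(x):
            return ModelPeriodMetrics(
                mape=x["mape"], mape_se=x["mape_se"], rmse=x["rmse"],
                bland_altman=BlandAltmanResult(**x["bland_altman"]),
                n_points=x["n_points"])
        return cls(
            convention=d["convention"],
            n_test_subjects=d["n_test_subjects"],
            n_stages=d["n_stages"],
            per_period={mdl: {per: metrics(met) for per, met in v.items()}
                        for mdl, v in d["per_period"].items()},
            overall={mdl: metrics(met) for mdl, met in d["overall"].items()},
            stage_mape={mdl: list(v) for mdl, v in d["stage_mape"].items()},
            stages_above_15=dict(d["stages_above_15"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "ValidationReport":
        return cls.from_dict(json.loads(s))


def _metrics(frame: pd.DataFrame, convention: str) -> ModelPeriodMetrics:
    m = frame["measured"].to_numpy()
    p = frame["predicted"].to_numpy()
    per_subject = [
        mape(g["measured"].to_numpy(), g["predicted"].to_numpy(), convention)
        for _, g in frame.groupby("subject_id")]
    se = (float(np.std(per_subject, ddof=1) / np.sqrt(len(per_subject)))
          if len(per_subject) > 1 else 0.0)
    return ModelPeriodMetrics(
        mape=mape(m, p, convention), mape_se=se, rmse=rmse(m, p),
        bland_altman=bland_altman(m, p), n_points=len(frame))


def evaluate_predictions(predictions: Mapping[str, pd.DataFrame],
                         n_stages: int,
                         convention: str = MEASURED_DENOMINATOR
                         ) -> ValidationReport:
    """Assemble the comparative report from per-model prediction frames.

    Each frame must hold one row per predicted window with columns
    ``subject_id, window_index, stage_index, period, measured, predicted``;
    exercise- and interval-period models must already have been applied to
    their matching windows.
    """
    per_period: dict = {}
    overall: dict = {}
    stage_mapes: dict = {}
    above: dict = {}
    n_subjects = 0
    for mdl, frame in predictions.items():
        required = {"subject_id", "stage_index", "period",
                    "measured", "predicted"}
        if not required <= set(frame.columns):
            raise ValueError(f"prediction frame for {mdl!r} lacks "
                             f"{sorted(required - set(frame.columns))}")
        n_subjects = max(n_subjects, frame["subject_id"].nunique())
        per_period[mdl] = {
            per: _metrics(grp, convention)
            for per, grp in frame.groupby("period")}
        overall[mdl] = _metrics(frame, convention)
        sm, cnt = per_stage_mape(frame["measured"], frame["predicted"],
                                 frame["stage_index"], n_stages, convention)
        stage_mapes[mdl] = sm
        above[mdl] = cnt
    return ValidationReport(
        convention=convention, n_test_subjects=n_subjects,
        n_stages=n_stages, per_period=per_period, overall=overall,
        stage_mape=stage_mapes, stages_above_15=above)
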