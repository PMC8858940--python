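"""Windowed feature construction from raw session streams.

Segments a session by its interval protocol into labeled, non-overlapping
10-s (by default) windows and computes, per window, the vector-magnitude
(VM) aggregate of the tri-axial counts, ten distributional statistics of the
per-sample VM values, the mean heart rate, and attached anthropometrics.
These rows are the common input record for both the regression and the
neural-network energy-expenditure models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import SessionData, SubjectProfile, TabataProtocol

EXERCISE = "exercise"
INTERVAL = "interval"

#: the 14 model-input features, in canonical order:
#: 10 VM window statistics + window-mean HR + height, weight, sex code
FEATURE_COLUMNS = [
    "vm_mean", "vm_sd", "vm_cov_adjacent", "vm_min", "vm_max",
    "vm_p10", "vm_p25", "vm_p50", "vm_p75", "vm_p90",
    "hr_mean", "height", "weight", "sex_code",
]


@dataclass(frozen=True)
class Window:
    window_index: int
    stage_index: int
    period: str  # EXERCISE | INTERVAL
    start_s: int
    end_s: int  # half-open [start_s, end_s)


@dataclass(frozen=True)
class WindowPlan:
    """Ordered, contiguous, half-open partition of a session into windows."""

    protocol: TabataProtocol
    windows: tuple[Window, ...]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass
class WindowFeatureRow:
    """Per-window VM statistics, HR aggregate and anthropometrics."""

    window_index: int
    stage_index: int
    period: str
    site: str
    vm_sum: float  # summed per-sample VM over the window (the VM value)
    vm_mean: float
    vm_sd: float
    vm_cov_adjacent: float
    vm_min: float
    vm_max: float
    vm_p10: float
    vm_p25: float
    vm_p50: float
    vm_p75: float
    vm_p90: float
    hr_mean: float
    height: float
    weight: float
    sex_code: int

    def features(self) -> np.ndarray:
        """The 14 model inputs in :data:`FEATURE_COLUMNS` order."""
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS],
                        dtype=float)


@dataclass(frozen=True)
class IntensitySummary:
    """Exercise-intensity description of one session."""

    mean_exercise_hr: float  # bpm over exercise seconds
    max_hr: float  # bpm
    mean_mets: float  # MET over exercise windows
    pct_hrmax: float  # max observed HR as % of (220 - age)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_window_plan(protocol: TabataProtocol) -> WindowPlan:
    """Partition the protocol into labeled windows.

    Each stage contributes ``exercise_s / window_s`` exercise windows
    followed by ``interval_s / window_s`` interval windows; the classic
    8 x (20 + 10) protocol yields 24 windows in the pattern (E, E, I) x 8.
    """
    w = protocol.window_s
    windows = []
    t = 0
    idx = 0
    for stage in range(protocol.n_stages):
        for _ in range(protocol.exercise_s // w):
            windows.append(Window(idx, stage, EXERCISE, t, t + w))
            t += w
            idx += 1
        for _ in range(protocol.interval_s // w):
            windows.append(Window(idx, stage, INTERVAL, t, t + w))
            t += w
            idx += 1
    return WindowPlan(protocol=protocol, windows=tuple(windows))


def per_sample_vm(counts: np.ndarray) -> np.ndarray:
    """Per-sample vector magnitude sqrt(x^2 + y^2 + z^2) of tri-axial counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("counts must be an (n, 3) array")
    return np.sqrt((counts**2).sum(axis=1))


def vector_magnitude(counts: np.ndarray, start: int, end: int,
                     sampling_rate: int = 1) -> float:
    """Summed per-sample VM over the half-open window [start, end) seconds.

    With ``sampling_rate`` 1 the bounds index samples directly.
    """
    lo, hi = start * sampling_rate, end * sampling_rate
    if hi <= lo:
        raise ValueError("empty window")
    if lo < 0 or hi > len(counts):
        raise ValueError("window outside the series")
    return float(per_sample_vm(counts[lo:hi]).sum())


def _fill_hr_gaps(hr: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs; reject gaps longer than a window."""
    hr = np.asarray(hr, dtype=float)
    if not np.isnan(hr).any():
        return hr
    isnan = np.isnan(hr)
    # longest NaN run
    run, longest = 0, 0
    for v in isnan:
        run = run + 1 if v else 0
        longest = max(longest, run)
    if longest >= max_gap:
        raise ValueError(
            f"heart-rate gap of {longest} s exceeds the window length")
    return (pd.Series(hr)
            .interpolate(limit_direction="both")
            .to_numpy())


def window_features(counts: np.ndarray, hr: np.ndarray, plan: WindowPlan,
                    subject: SubjectProfile, site: str,
                    sampling_rate: int = 30) -> list[WindowFeatureRow]:
    """Compute one :class:`WindowFeatureRow` per window of the plan.

    Percentiles use linear interpolation between order statistics; the
    adjacent covariance of window *w* is the sample covariance (n-1 in the
    denominator) between the per-sample VM vectors of windows *w-1* and *w*,
    and 0 for the first window.
    """
    protocol = plan.protocol
    spw = protocol.window_s * sampling_rate
    n_samples = protocol.duration_s * sampling_rate
    counts = np.asarray(counts, dtype=float)
    if len(counts) != n_samples:
        raise ValueError(
            f"count series has {len(counts)} samples; plan needs {n_samples}")
    if len(hr) != protocol.duration_s:
        raise ValueError(
            f"hr series has {len(hr)} s; plan needs {protocol.duration_s}")
    hr = _fill_hr_gaps(np.asarray(hr, dtype=float), protocol.window_s)

    vm = per_sample_vm(counts).reshape(len(plan), spw)
    hrw = hr.reshape(len(plan), protocol.window_s)

    mean = vm.mean(axis=1)
    sd = vm.std(axis=1, ddof=1)
    pcts = np.percentile(vm, [10, 25, 50, 75, 90], axis=1)
    # adjacent-window covariance, vectorised: cov(v_{w-1}, v_w), first = 0
    centered = vm - mean[:, None]
    cov_adj = np.zeros(len(plan))
    if len(plan) > 1:
        cov_adj[1:] = (centered[:-1] * centered[1:]).sum(axis=1) / (spw - 1)

    rows = []
    for w in plan:
        i = w.window_index
        rows.append(WindowFeatureRow(
            window_index=i, stage_index=w.stage_index, period=w.period,
            site=site,
            vm_sum=float(vm[i].sum()),
            vm_mean=float(mean[i]), vm_sd=float(sd[i]),
            vm_cov_adjacent=float(cov_adj[i]),
            vm_min=float(vm[i].min()), vm_max=float(vm[i].max()),
            vm_p10=float(pcts[0, i]), vm_p25=float(pcts[1, i]),
            vm_p50=float(pcts[2, i]), vm_p75=float(pcts[3, i]),
            vm_p90=float(pcts[4, i]),
            hr_mean=float(hrw[i].mean()),
            height=subject.height, weight=subject.weight,
            sex_code=subject.sex_code,
        ))
    return rows


def stage_vm(rows: Sequence[WindowFeatureRow], stage: int) -> float:
    """Summed window VM over the whole stage (exercise + interval windows)."""
    vals = [r.vm_sum for r in rows if r.stage_index == stage]
    if not vals:
        raise ValueError(f"stage {stage} not present in rows")
    return float(sum(vals))


def intensity_summary(hr: np.ndarray, ee: np.ndarray,
                      subject: SubjectProfile,
                      plan: WindowPlan) -> IntensitySummary:
    """Session intensity: exercise-mean HR, max HR, exercise METs, %HRmax.

    METs convert kcal per window via 1 MET = 1 kcal/kg/h; %HRmax uses the
    conventional 220 - age estimate of maximum heart rate.
    """
    hr = np.asarray(hr, dtype=float)
    ee = np.asarray(ee, dtype=float)
    if hr.size == 0 or ee.size == 0:
        raise ValueError("empty series")
    if subject.weight <= 0:
        raise ValueError("subject weight must be positive")
    ex_seconds = np.concatenate(
        [np.arange(w.start_s, w.end_s) for w in plan if w.period == EXERCISE])
    ex_windows = [w.window_index for w in plan if w.period == EXERCISE]
    mets = ee[ex_windows] * (3600.0 / plan.protocol.window_s) / subject.weight
    max_hr = float(hr.max())
    return IntensitySummary(
        mean_exercise_hr=float(hr[ex_seconds].mean()),
        max_hr=max_hr,
        mean_mets=float(mets.mean()),
        pct_hrmax=100.0 * max_hr / (220.0 - subject.age),
    )


# ---------------------------------------------------------------------------
# tabular assembly (feature frames and model design matrices)
# ---------------------------------------------------------------------------

def session_features(session: SessionData,
                     plan: WindowPlan | None = None) -> pd.DataFrame:
    """All-site feature table for one session: one row per (site, window)."""
    plan = plan or build_window_plan(session.protocol)
    frames = []
    for site, counts in session.counts.items():
        rows = window_features(counts, session.hr, plan, session.subject,
                               site, session.sampling_rate)
        df = pd.DataFrame([r.__dict__ for r in rows])
        df.insert(0, "subject_id", session.subject.subject_id)
        df["age"] = session.subject.age
        df["bmi"] = session.subject.bmi
        df["body_fat"] = session.subject.body_fat
        df["ee"] = session.ee[df["window_index"].to_numpy()]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_features(sessions: Iterable[SessionData]) -> pd.DataFrame:
    """Feature table for a whole cohort (one row per subject, site, window)."""
    return pd.concat([session_features(s) for s in sessions],
                     ignore_index=True)


def exercise_design(features: pd.DataFrame) -> pd.DataFrame:
    """Exercise-period design: one row per (subject, exercise window).

    Candidate predictors are the per-window VM of each wear site
    (``vm_<site>``), the window-mean exercise HR (``hr_exercise``) and the
    anthropometrics; the target column is ``ee``.
    """
    ex = features[features["period"] == EXERCISE]
    wide = ex.pivot_table(index=["subject_id", "window_index"],
                          columns="site", values="vm_sum")
    wide.columns = [f"vm_{c}" for c in wide.columns]
    meta_cols = ["stage_index", "hr_mean", "height", "weight", "sex_code",
                 "age", "bmi", "body_fat", "ee"]
    meta = (ex.groupby(["subject_id", "window_index"])[meta_cols]
            .first())
    out = wide.join(meta).reset_index()
    return out.rename(columns={"hr_mean": "hr_exercise"})


def interval_design(features: pd.DataFrame,
                    site: str = "right_ankle") -> pd.DataFrame:
    """Interval-period design: one row per (subject, interval window).

    Candidate predictors are the stage-level VM/HR aggregates of the
    reference site — VM over 0-10 s, 10-20 s, 0-20 s of exercise and over
    the entire stage; HR over the same spans and during the interval —
    plus the anthropometrics.  Assumes the classic two-exercise-window,
    one-interval-window stage layout.
    """
    sub = features[features["site"] == site]
    rows = []
    for (sid, stage), grp in sub.groupby(["subject_id", "stage_index"]):
        grp = grp.sort_values("window_index")
        ex = grp[grp["period"] == EXERCISE]
        ivl = grp[grp["period"] == INTERVAL]
        if len(ex) != 2 or len(ivl) < 1:
            raise ValueError(
                "interval_design expects 2 exercise + >=1 interval windows "
                "per stage (classic 20-10 protocol)")
        first = grp.iloc[0]
        base = {
            "subject_id": sid, "stage_index": stage,
            "vm_exe_0_10": ex.iloc[0]["vm_sum"],
            "vm_exe_10_20": ex.iloc[1]["vm_sum"],
            "vm_exe_0_20": ex["vm_sum"].sum(),
            "vm_stage": grp["vm_sum"].sum(),
            "hr_exe_0_10": ex.iloc[0]["hr_mean"],
            "hr_exe_10_20": ex.iloc[1]["hr_mean"],
            "hr_exe_0_20": ex["hr_mean"].mean(),
            "hr_stage": grp["hr_mean"].mean(),
            "height": first["height"], "weight": first["weight"],
            "sex_code": first["sex_code"], "age": first["age"],
            "bmi": first["bmi"], "body_fat": first["body_fat"],
        }
        for _, irow in ivl.iterrows():
            rows.append(dict(base, window_index=irow["window_index"],
                             hr_interval=irow["hr_mean"], ee=irow["ee"]))
    return pd.DataFrame(rows)


def period_feature_matrix(features: pd.DataFrame, period: str,
                          site: str = "right_ankle") -> pd.DataFrame:
    """The 14-column network input frame for one period, with metadata."""
    sub = features[(features["site"] == site)
                   & (features["period"] == period)]
    cols = ["subject_id", "window_index", "stage_index"] + FEATURE_COLUMNS + ["ee"]
    return sub[cols].reset_index(drop=True)
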