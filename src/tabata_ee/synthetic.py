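"""Synthetic Tabata sensor-stream generator.

Simulates the three measurement channels of a Tabata energy-expenditure
study — tri-axial accelerometer counts at several wear sites, a per-second
heart-rate trace, and per-window energy expenditure (EE, kcal) from indirect
calorimetry — for cohorts of subjects with realistic anthropometrics.

The generator is a first-class, seeded component: every draw is a pure
function of (config, seed), and the default configuration reproduces the
intensity profile of a classic 8 x (20 s exercise + 10 s standing interval)
session performed by young adults (exercise heart rate plateau ~165 bpm,
~8.8 METs during the bouts, near-zero counts while standing).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

SITES = ("dominant_hand", "nondominant_hand", "right_hip", "right_ankle")

#: counts per sample per axis during exercise bouts, by wear site.  The ankle
#: moves most in jump-based movements, the hip least.
DEFAULT_SITE_SCALES = {
    "dominant_hand": 60.0,
    "nondominant_hand": 55.0,
    "right_hip": 50.0,
    "right_ankle": 75.0,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and identity of one (real or simulated) participant."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years
    height: float  # m
    weight: float  # kg
    bmi: float  # kg/m^2
    body_fat: float  # percent

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age <= 0 or self.height <= 0 or self.weight <= 0:
            raise ValueError("age, height and weight must be strictly positive")
        if abs(self.bmi - self.weight / self.height**2) > 0.1:
            raise ValueError("bmi inconsistent with weight/height^2")
        if not 0.0 <= self.body_fat <= 100.0:
            raise ValueError("body_fat must lie in [0, 100]")

    @property
    def sex_code(self) -> int:
        """0 for female, 1 for male (the convention used in model inputs)."""
        return 1 if self.sex == "male" else 0


@dataclass(frozen=True)
class TabataProtocol:
    """Stage structure of an interval session, partitioned into windows."""

    n_stages: int = 8
    exercise_s: int = 20
    interval_s: int = 10
    window_s: int = 10

    def __post_init__(self) -> None:
        for name in ("n_stages", "exercise_s", "interval_s", "window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exercise_s % self.window_s or self.interval_s % self.window_s:
            raise ValueError(
                "exercise_s and interval_s must each be divisible by window_s"
            )

    @classmethod
    def classic(cls) -> "TabataProtocol":
        """The classic 20-10 mode: 8 stages of 20 s exercise + 10 s interval."""
        return cls(8, 20, 10, 10)

    @property
    def stage_s(self) -> int:
        return self.exercise_s + self.interval_s

    @property
    def duration_s(self) -> int:
        return self.n_stages * self.stage_s

    @property
    def n_windows(self) -> int:
        return self.duration_s // self.window_s


@dataclass
class SessionData:
    """One subject's full session: counts per site, HR trace, measured EE."""

    subject: SubjectProfile
    protocol: TabataProtocol
    sampling_rate: int  # Hz of the count series
    counts: dict[str, np.ndarray]  # site -> (n_samples, 3) nonnegative
    hr: np.ndarray  # (duration_s,) bpm
    ee: np.ndarray  # (n_windows,) kcal per window

    def __post_init__(self) -> None:
        n_samples = self.protocol.duration_s * self.sampling_rate
        for site, arr in self.counts.items():
            if arr.shape != (n_samples, 3):
                raise ValueError(f"counts[{site}] has shape {arr.shape}, "
                                 f"expected {(n_samples, 3)}")
            if np.any(arr < 0):
                raise ValueError(f"counts[{site}] contains negative values")
        if self.hr.shape != (self.protocol.duration_s,):
            raise ValueError("hr length must equal protocol duration in seconds")
        if np.any(self.hr < 30) or np.any(self.hr > 230):
            raise ValueError("hr outside the plausible [30, 230] bpm range")
        if self.ee.shape != (self.protocol.n_windows,):
            raise ValueError("ee length must equal the protocol window count")
        if np.any(self.ee < 0):
            raise ValueError("ee must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """All population and signal parameters of the generator.

    Anthropometric means/SDs default to a young-adult cohort (n = 45-like:
    age 21.04 +/- 2.39 y, height 1.67 +/- 0.075 m, weight 59.61 +/- 8.27 kg,
    body fat 18.46 +/- 5.47 %).  Heart-rate kinetics follow first-order
    on/off responses around a per-subject exercise plateau (165.46 +/- 5.39
    bpm for men, 163.88 +/- 6.88 for women).  EE per window is a linear
    function of the reference-site window vector magnitude (VM), the window
    mean HR and body weight, with an optional intensity-curvature term and
    additive Gaussian noise, floored at zero.
    """

    protocol: TabataProtocol = field(default_factory=TabataProtocol.classic)
    sampling_rate: int = 30  # Hz

    # anthropometrics
    female_fraction: float = 23 / 45
    age_mean: float = 21.04
    age_sd: float = 2.39
    height_mean: float = 1.67
    height_sd: float = 0.075
    weight_mean: float = 59.61
    weight_sd: float = 8.27
    body_fat_mean: float = 18.46
    body_fat_sd: float = 5.47

    # heart-rate kinetics (bpm, s)
    hr_plateau_male: float = 165.46
    hr_plateau_sd_male: float = 5.39
    hr_plateau_female: float = 163.88
    hr_plateau_sd_female: float = 6.88
    hr_recovery_drop: float = 10.0  # interval decay target = plateau - drop
    hr_tau_on: float = 15.0
    hr_tau_off: float = 40.0
    hr_noise_sd: float = 2.0

    # accelerometer counts
    site_scales: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_SCALES))
    interval_scale: float = 2.0  # counts/sample/axis while standing
    window_intensity_cv: float = 0.25  # per-(site, window) effort multiplier
    subject_intensity_cv: float = 0.15  # per-subject effort multiplier

    # EE generative model (kcal per window)
    ee_site: str = "right_ankle"
    ee_vm_coef: float = 0.5e-5
    ee_hr_coef: float = 0.018
    ee_weight_coef: float = 0.008
    ee_intercept: float = -2.2
    ee_vm_ref: float = 40000.0  # reference exercise-window VM for curvature
    nonlinearity_gain: float = 1.0
    ee_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        sds = (self.age_sd, self.height_sd, self.weight_sd, self.body_fat_sd,
               self.hr_plateau_sd_male, self.hr_plateau_sd_female,
               self.hr_noise_sd, self.ee_noise_sd,
               self.window_intensity_cv, self.subject_intensity_cv)
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be nonnegative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.ee_site not in self.site_scales:
            raise ValueError(f"ee_site {self.ee_site!r} has no site scale")


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean, sd, size=None,
                      low: float = 0.0) -> np.ndarray | float:
    """Normal(mean, sd) with draws below `low` rejected and resampled."""
    if np.all(np.asarray(sd) == 0):
        out = np.broadcast_to(np.asarray(mean, dtype=float), size or ()).copy()
        if np.any(out < low):
            raise ValueError("degenerate truncated normal below bound")
        return out if size else float(out)
    x = rng.normal(mean, sd, size)
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    bad = x < low
    for _ in range(1000):
        if not bad.any():
            break
        x[bad] = rng.normal(np.broadcast_to(mean, x.shape)[bad]
                            if np.ndim(mean) else mean,
                            sd, int(bad.sum()))
        bad = x < low
    else:  # pragma: no cover - requires pathological parameters
        raise RuntimeError("truncated-normal rejection did not converge")
    return float(x[0]) if scalar else x


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_subject(config: SimulationConfig, seed: int,
                     subject_id: str | None = None) -> SubjectProfile:
    """Draw one subject profile from the configured population.

    All quantities come from truncated-normal distributions (non-positive
    draws are rejected), BMI is recomputed from the drawn height and weight,
    and the same seed always yields the identical profile.
    """
    rng = np.random.default_rng(seed)
    sex = "female" if rng.random() < config.female_fraction else "male"
    age = _truncated_normal(rng, config.age_mean, config.age_sd, low=1e-6)
    height = _truncated_normal(rng, config.height_mean, config.height_sd,
                               low=1e-6)
    weight = _truncated_normal(rng, config.weight_mean, config.weight_sd,
                               low=1e-6)
    body_fat = _truncated_normal(rng, config.body_fat_mean, config.body_fat_sd,
                                 low=0.0)
    return SubjectProfile(
        subject_id=subject_id or f"S{seed}",
        sex=sex,
        age=age,
        height=height,
        weight=weight,
        bmi=weight / height**2,
        body_fat=min(body_fat, 100.0),
    )


def _exercise_mask_seconds(protocol: TabataProtocol) -> np.ndarray:
    """Boolean per-second mask: True during exercise bouts."""
    stage = np.r_[np.ones(protocol.exercise_s, bool),
                  np.zeros(protocol.interval_s, bool)]
    return np.tile(stage, protocol.n_stages)


def _window_labels(protocol: TabataProtocol) -> np.ndarray:
    """Boolean per-window mask: True for exercise windows."""
    per_stage = np.r_[
        np.ones(protocol.exercise_s // protocol.window_s, bool),
        np.zeros(protocol.interval_s // protocol.window_s, bool)]
    return np.tile(per_stage, protocol.n_stages)


def _simulate_hr(subject: SubjectProfile, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """First-order on/off HR kinetics around the subject's plateau.

    The trace starts at the steady inter-bout level (plateau minus the
    recovery drop) so the exercise-period mean sits at the configured
    plateau, emulating a session recorded after the initial on-transient.
    """
    if subject.sex == "male":
        plateau = _truncated_normal(rng, config.hr_plateau_male,
                                    config.hr_plateau_sd_male, low=60.0)
    else:
        plateau = _truncated_normal(rng, config.hr_plateau_female,
                                    config.hr_plateau_sd_female, low=60.0)
    protocol = config.protocol
    exercising = _exercise_mask_seconds(protocol)
    hr = np.empty(protocol.duration_s)
    level = plateau - config.hr_recovery_drop
    for t in range(protocol.duration_s):
        if exercising[t]:
            target, tau = plateau, config.hr_tau_on
        else:
            target, tau = plateau - config.hr_recovery_drop, config.hr_tau_off
        level = target + (level - target) * np.exp(-1.0 / tau)
        hr[t] = level
    hr = hr + rng.normal(0.0, config.hr_noise_sd, hr.shape)
    cap = min(220.0 - subject.age, 230.0)
    return np.clip(hr, 30.0, cap)


def _simulate_counts(config: SimulationConfig, rng: np.random.Generator,
                     subject_factor: float,
                     sites: Sequence[str]) -> dict[str, np.ndarray]:
    protocol = config.protocol
    rate = config.sampling_rate
    spw = protocol.window_s * rate  # samples per window
    n_windows = protocol.n_windows
    exercise_win = _window_labels(protocol)
    counts: dict[str, np.ndarray] = {}
    for site in sites:
        scale = config.site_scales[site]
        # per-(site, window) effort multiplier: movements differ and
        # subjects fatigue, so between-window intensity varies
        mult = _truncated_normal(
            rng, 1.0, config.window_intensity_cv, size=n_windows, low=0.05)
        mult = np.where(exercise_win, mult * subject_factor, 1.0)
        arr = np.empty((n_windows, spw, 3))
        for w in range(n_windows):
            if exercise_win[w]:
                m, s = scale * mult[w], scale * mult[w] / 3.0
            else:
                m, s = config.interval_scale, config.interval_scale / 2.0
            if m == 0 and s == 0:
                arr[w] = 0.0
            else:
                arr[w] = _truncated_normal(rng, m, s, size=(spw, 3), low=0.0)
        counts[site] = arr.reshape(n_windows * spw, 3)
    return counts


def _window_vm_sums(counts: np.ndarray, protocol: TabataProtocol,
                    rate: int) -> np.ndarray:
    vm = np.sqrt((counts**2).sum(axis=1))
    return vm.reshape(protocol.n_windows, protocol.window_s * rate).sum(axis=1)


def simulate_session(subject: SubjectProfile, config: SimulationConfig,
                     seed: int,
                     sites: Sequence[str] = SITES) -> SessionData:
    """Simulate one full session for `subject`.

    Exercise-second counts are truncated normals at the site's intensity
    scale (modulated per window and per subject); interval counts sit at the
    near-zero standing level, exactly zero when ``interval_scale`` is 0.
    HR rises toward the bout plateau and decays during intervals.  Per-window
    EE is the configured function of window VM (reference site), window-mean
    HR and body weight, plus an exercise-only intensity-curvature term and
    Gaussian noise, floored at 0.
    """
    protocol = config.protocol
    if protocol.duration_s <= 0:
        raise ValueError("protocol duration must be positive")
    if config.ee_site not in sites:
        raise ValueError(f"sites must include the EE reference site "
                         f"{config.ee_site!r}")
    rng = np.random.default_rng(seed)
    subject_factor = _truncated_normal(
        rng, 1.0, config.subject_intensity_cv, low=0.05)
    counts = _simulate_counts(config, rng, subject_factor, sites)
    hr = _simulate_hr(subject, config, rng)

    vm_win = _window_vm_sums(counts[config.ee_site], protocol,
                             config.sampling_rate)
    hr_win = hr.reshape(protocol.n_windows, protocol.window_s).mean(axis=1)
    exercise_win = _window_labels(protocol)

    ee = (config.ee_vm_coef * vm_win
          + config.ee_hr_coef * hr_win
          + config.ee_weight_coef * subject.weight
          + config.ee_intercept)
    # curvature of the EE-intensity relation during the bouts only:
    # near-resting intervals are treated as linear
    rel = vm_win / config.ee_vm_ref
    ee = ee + np.where(exercise_win,
                       config.nonlinearity_gain * (rel - 1.0) ** 2, 0.0)
    ee = ee + rng.normal(0.0, config.ee_noise_sd, ee.shape)
    ee = np.maximum(ee, 0.0)

    return SessionData(subject=subject, protocol=protocol,
                       sampling_rate=config.sampling_rate,
                       counts=counts, hr=hr, ee=ee)


def simulate_cohort(config: SimulationConfig, n_subjects: int, seed: int,
                    sites: Sequence[str] = SITES) -> list[SessionData]:
    """Simulate `n_subjects` independent sessions, seeded from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    sessions = []
    for i, child in enumerate(children):
        sub_seed, ses_seed = child.generate_state(2) >> 1  # keep < 2**31
        subject = simulate_subject(config, int(sub_seed),
                                   subject_id=f"S{i:03d}")
        sessions.append(simulate_session(subject, config, int(ses_seed),
                                         sites=sites))
    return sessions


# ---------------------------------------------------------------------------
# cohort writers / readers (plain CSV + YAML manifest)
# ---------------------------------------------------------------------------

def write_cohort(sessions: Sequence[SessionData], out_dir: str | Path,
                 config: SimulationConfig | None = None,
                 seed: int | None = None) -> Path:
    """Write a cohort directory: subjects.csv, per-subject channel CSVs,
    and a YAML manifest recording the config and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "subjects.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["subject_id", "sex", "age", "height", "weight",
                     "bmi", "body_fat"])
        for s in sessions:
            p = s.subject
            wr.writerow([p.subject_id, p.sex, repr(float(p.age)),
                         repr(float(p.height)), repr(float(p.weight)),
                         repr(float(p.bmi)), repr(float(p.body_fat))])
    for s in sessions:
        sdir = out / s.subject.subject_id
        sdir.mkdir(exist_ok=True)
        for site, arr in s.counts.items():
            with open(sdir / f"counts_{site}.csv", "w", newline="") as fh:
                wr = csv.writer(fh)
                wr.writerow(["sample_index", "x", "y", "z"])
                for i, (x, y, z) in enumerate(arr):
                    wr.writerow([i, repr(float(x)), repr(float(y)),
                                 repr(float(z))])
        with open(sdir / "hr.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["second", "bpm"])
            for i, v in enumerate(s.hr):
                wr.writerow([i, repr(float(v))])
        with open(sdir / "ee.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["window_index", "kcal"])
            for i, v in enumerate(s.ee):
                wr.writerow([i, repr(float(v))])
    manifest = {
        "n_subjects": len(sessions),
        "seed": seed,
        "sites": sorted({site for s in sessions for site in s.counts}),
        "protocol": dataclasses.asdict(sessions[0].protocol) if sessions else None,
        "sampling_rate": sessions[0].sampling_rate if sessions else None,
        "config": _config_to_dict(config) if config is not None else None,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["protocol"] = dataclasses.asdict(config.protocol)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if isinstance(d.get("protocol"), dict):
        d["protocol"] = TabataProtocol(**d["protocol"])
    return SimulationConfig(**d)


def read_cohort(cohort_dir: str | Path) -> list[SessionData]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    with open(root / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    protocol = TabataProtocol(**manifest["protocol"])
    rate = manifest["sampling_rate"]
    subjects = {}
    with open(root / "subjects.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            subjects[row["subject_id"]] = SubjectProfile(
                subject_id=row["subject_id"], sex=row["sex"],
                age=float(row["age"]), height=float(row["height"]),
                weight=float(row["weight"]), bmi=float(row["bmi"]),
                body_fat=float(row["body_fat"]))
    sessions = []
    for sid, subject in subjects.items():
        sdir = root / sid
        counts = {}
        for site in manifest["sites"]:
            data = np.loadtxt(sdir / f"counts_{site}.csv", delimiter=",",
                              skiprows=1, ndmin=2)
            counts[site] = data[:, 1:4]
        hr = np.loadtxt(sdir / "hr.csv", delimiter=",", skiprows=1,
                        ndmin=2)[:, 1]
        ee = np.atleast_1d(np.loadtxt(sdir / "ee.csv", delimiter=",",
                                      skiprows=1, ndmin=2)[:, 1])
        sessions.append(SessionData(subject=subject, protocol=protocol,
                                    sampling_rate=rate, counts=counts,
                                    hr=hr, ee=ee))
    return sessions
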