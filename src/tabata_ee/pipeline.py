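"""End-to-end orchestration: simulate -> features -> fit -> validate.

One :class:`PipelineConfig` (YAML-serialisable, single global seed) drives
the whole chain and yields a :class:`~tabata_ee.validation.ValidationReport`
comparing the stepwise linear-regression and BPNN energy-expenditure models
on held-out subjects.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bpnn, models, validation
from .features import (EXERCISE, FEATURE_COLUMNS, INTERVAL, cohort_features,
                       exercise_design, interval_design,
                       period_feature_matrix)
from .synthetic import (SimulationConfig, config_from_dict, simulate_cohort,
                        write_cohort, _config_to_dict)
from .validation import ValidationReport, evaluate_predictions

log = logging.getLogger("tabata_ee")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full experiment."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_subjects: int = 45
    site: str = "right_ankle"  # reference wear site for NN/interval designs
    p_enter: float = 0.05
    p_remove: float = 0.10
    train: bpnn.TrainConfig = field(default_factory=bpnn.TrainConfig)
    hidden_exercise: int = 6  # fixed hidden width for the exercise net
    hidden_interval: int = 10  # fixed hidden width for the interval net
    hidden_search: bool = False  # sweep candidates instead of fixed widths
    hidden_candidates: list[int] | None = None  # None -> heuristic range
    ratio_train: float = 0.75
    n_test: int | None = None
    mape_convention: str = validation.MEASURED_DENOMINATOR
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"] = _config_to_dict(self.sim)
        d["train"] = dataclasses.asdict(self.train)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if isinstance(d.get("sim"), dict):
            d["sim"] = config_from_dict(d["sim"])
        if isinstance(d.get("train"), dict):
            d["train"] = bpnn.TrainConfig(**d["train"])
        return cls(**d)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds (< 2^31) from one global seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) >> 1]


def _nn_prediction_frame(model, matrix: pd.DataFrame) -> pd.DataFrame:
    pred = bpnn.predict_ee(model, matrix[FEATURE_COLUMNS].to_numpy())
    return pd.DataFrame({
        "subject_id": matrix["subject_id"],
        "window_index": matrix["window_index"],
        "stage_index": matrix["stage_index"],
        "measured": matrix["ee"], "predicted": pred})


def _lr_prediction_frame(spec, design: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": design["subject_id"],
        "window_index": design["window_index"],
        "stage_index": design["stage_index"],
        "measured": design["ee"], "predicted": spec.predict(design)})


@dataclass
class PipelineResult:
    report: ValidationReport
    lr_models: dict  # period -> LinearModelSpec
    nn_models: dict  # period -> NetworkModel
    nn_hidden: dict  # period -> chosen width
    correlations: pd.DataFrame
    predictions: dict  # model -> prediction frame (test subjects)
    train_ids: list[str]
    test_ids: list[str]
    features: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole experiment described by ``config``.

    Fully reproducible from (config, seed): simulation, the subject split,
    stepwise selection and both network fits derive their seeds from the
    single global seed.
    """
    t0 = time.perf_counter()
    sim_seed, split_seed, nn_ex_seed, nn_int_seed = derive_seeds(config.seed, 4)

    def stage(name):
        log.info("[%7.2f s] %s", time.perf_counter() - t0, name)

    stage(f"simulate: {config.n_subjects} subjects, seed {sim_seed}")
    sessions = simulate_cohort(config.sim, config.n_subjects, sim_seed)
    n_stages = config.sim.protocol.n_stages

    stage("features: windowed VM/HR statistics for all sites")
    feats = cohort_features(sessions)
    ex_design = exercise_design(feats)
    int_design = interval_design(feats, site=config.site)
    nn_ex = period_feature_matrix(feats, EXERCISE, site=config.site)
    nn_int = period_feature_matrix(feats, INTERVAL, site=config.site)

    stage("split: subject-level train/test")
    ids = sorted(feats["subject_id"].unique())
    train_ids, test_ids = validation.split_subjects(
        ids, config.ratio_train, seed=split_seed, n_test=config.n_test)

    def tr(df):
        return df[df["subject_id"].isin(train_ids)]

    def te(df):
        return df[df["subject_id"].isin(test_ids)]

    stage("screen: Pearson correlation of candidates vs EE (training set)")
    corr = pd.concat([
        models.correlation_table(tr(ex_design), models.EXERCISE_CANDIDATES,
                                 EXERCISE),
        models.correlation_table(tr(int_design), models.INTERVAL_CANDIDATES,
                                 INTERVAL),
    ], ignore_index=True)

    stage("fit: stepwise linear regression per period")
    lr_ex = models.stepwise_fit(tr(ex_design),
                                candidates=models.EXERCISE_CANDIDATES,
                                p_enter=config.p_enter,
                                p_remove=config.p_remove, period=EXERCISE)
    lr_int = models.stepwise_fit(tr(int_design),
                                 candidates=models.INTERVAL_CANDIDATES,
                                 p_enter=config.p_enter,
                                 p_remove=config.p_remove, period=INTERVAL)

    stage("fit: back-propagation networks per period")
    nn_models, nn_hidden = {}, {}
    for period, matrix, fixed, seed in (
            (EXERCISE, nn_ex, config.hidden_exercise, nn_ex_seed),
            (INTERVAL, nn_int, config.hidden_interval, nn_int_seed)):
        X = tr(matrix)[FEATURE_COLUMNS].to_numpy()
        y = tr(matrix)["ee"].to_numpy()
        cfg = dataclasses.replace(config.train, seed=seed)
        if config.hidden_search:
            cands = (config.hidden_candidates
                     or bpnn.heuristic_hidden_range(len(FEATURE_COLUMNS), 1))
            width, rmses = bpnn.hidden_node_search(X, y, cands, cfg)
            log.info("hidden-node search (%s): %s -> %d", period,
                     {k: round(v, 4) for k, v in rmses.items()}, width)
        else:
            width = fixed
        model, history = bpnn.fit_bpnn(X, y, width, cfg)
        log.info("trained %d-%d-1 net (%s): %d epochs, final scaled MSE %.3g",
                 len(FEATURE_COLUMNS), width, period, len(history),
                 history[-1] if history else float("nan"))
        nn_models[period] = model
        nn_hidden[period] = width

    stage("evaluate: period-matched predictions on held-out subjects")
    predictions = {
        "linear_regression": pd.concat([
            _lr_prediction_frame(lr_ex, te(ex_design)).assign(period=EXERCISE),
            _lr_prediction_frame(lr_int, te(int_design)).assign(period=INTERVAL),
        ], ignore_index=True),
        "bpnn": pd.concat([
            _nn_prediction_frame(nn_models[EXERCISE], te(nn_ex)).assign(period=EXERCISE),
            _nn_prediction_frame(nn_models[INTERVAL], te(nn_int)).assign(period=INTERVAL),
        ], ignore_index=True),
    }
    report = evaluate_predictions(predictions, n_stages,
                                  convention=config.mape_convention)
    result = PipelineResult(
        report=report, lr_models={EXERCISE: lr_ex, INTERVAL: lr_int},
        nn_models=nn_models, nn_hidden=nn_hidden, correlations=corr,
        predictions=predictions, train_ids=train_ids, test_ids=test_ids,
        features=feats)

    if config.out_dir is not None:
        stage(f"write: artifacts under {config.out_dir}")
        write_artifacts(result, config, sessions)
    stage("done")
    return result


def write_artifacts(result: PipelineResult, config: PipelineConfig,
                    sessions=None) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    result.features.to_csv(out / "features.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    (out / "models.json").write_text(models_to_json(result))
    (out / "report.json").write_text(result.report.to_json())
    pred = pd.concat([f.assign(model=m)
                      for m, f in result.predictions.items()],
                     ignore_index=True)
    pred.to_csv(out / "predictions.csv", index=False)
    if sessions is not None:
        write_cohort(sessions, out / "cohort", config.sim, config.seed)


def models_to_json(result: PipelineResult) -> str:
    import json
    d = {
        "linear_regression": {p: s.to_dict()
                              for p, s in result.lr_models.items()},
        "bpnn": {p: json.loads(m.to_json())
                 for p, m in result.nn_models.items()},
        "nn_hidden": result.nn_hidden,
        "train_ids": result.train_ids,
        "test_ids": result.test_ids,
    }
    return json.dumps(d, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# figures (optional, headless)
# ---------------------------------------------------------------------------

def plot_bland_altman(predictions: pd.DataFrame, out_path: str | Path,
                      title: str = "") -> None:
    """Scatter of differences vs pairwise means with limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = predictions["measured"].to_numpy()
    p = predictions["predicted"].to_numpy()
    x, d = validation.bland_altman_points(m, p)
    res = validation.bland_altman(m, p)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, d, s=8, alpha=0.6)
    for yv, style in ((res.mean_diff, "-"),
                      (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of measured and predicted EE (kcal/window)")
    ax.set_ylabel("measured - predicted (kcal)")
    ax.set_title(title or f"{res.pct_within:.1f}% within limits")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_stage_mape(report: ValidationReport, out_path: str | Path) -> None:
    """Grouped per-stage MAPE bars for each model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(report.stage_mape)
    width = 0.8 / max(len(names), 1)
    stages = np.arange(report.n_stages)
    for i, name in enumerate(names):
        ax.bar(stages + i * width, report.stage_mape[name], width,
               label=name)
    ax.axhline(15.0, color="k", linestyle=":", linewidth=1)
    ax.set_xticks(stages + width * (len(names) - 1) / 2,
                  [str(s + 1) for s in stages])
    ax.set_xlabel("stage")
    ax.set_ylabel("MAPE (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
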