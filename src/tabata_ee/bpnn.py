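"""Single-hidden-layer back-propagation network for EE prediction.

A deliberately transparent, fully hand-written implementation: logistic
sigmoid (logsig) activations at both the hidden and output layer, batch
gradient descent on the mean squared error with a momentum term and an
adaptive learning rate (grow on improvement, shrink and discard the step
when the error inflates), min-max input scaling to [0, 1] and target
scaling to [0.1, 0.9] to keep the sigmoid output away from saturation.
Hidden-layer width is chosen by a square-root heuristic seeding a candidate
sweep scored by held-out RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

TARGET_LO, TARGET_HI = 0.1, 0.9


def logsig(x):
    """Logistic sigmoid 1 / (1 + e^-x), numerically stable for large |x|."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out[0]) if np.ndim(x) == 0 else out.reshape(np.shape(x))


def heuristic_hidden_range(n_input: int, n_output: int,
                           lo: int = 4, hi: int = 15) -> list[int]:
    """Hidden-node candidates: round(sqrt(n_in + n_out)) + c, c = 0..11,
    intersected with [lo, hi]."""
    if n_input <= 0 or n_output <= 0:
        raise ValueError("layer sizes must be positive")
    base = int(round(np.sqrt(n_input + n_output)))
    return [base + c for c in range(12) if lo <= base + c <= hi]


@dataclass
class Scaling:
    """Min-max ranges mapping raw features to [0, 1] and targets to
    [0.1, 0.9]; constant columns are given a unit span."""

    x_min: np.ndarray
    x_max: np.ndarray
    t_min: float
    t_max: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "Scaling":
        x_min = X.min(axis=0)
        x_max = X.max(axis=0)
        degenerate = x_max <= x_min
        x_max = np.where(degenerate, x_min + 1.0, x_max)
        t_min, t_max = float(y.min()), float(y.max())
        if t_max <= t_min:
            t_max = t_min + 1.0
        return cls(x_min=x_min, x_max=x_max, t_min=t_min, t_max=t_max)

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / (self.x_max - self.x_min)

    def scale_t(self, y: np.ndarray) -> np.ndarray:
        span = self.t_max - self.t_min
        return TARGET_LO + (TARGET_HI - TARGET_LO) * (y - self.t_min) / span

    def unscale_t(self, t: np.ndarray) -> np.ndarray:
        span = self.t_max - self.t_min
        return self.t_min + (t - TARGET_LO) / (TARGET_HI - TARGET_LO) * span


@dataclass
class NetworkModel:
    """Weights (with biases folded into the last column) and scaling."""

    n_input: int
    n_hidden: int
    n_output: int
    w1: np.ndarray  # (n_hidden, n_input + 1)
    w2: np.ndarray  # (n_output, n_hidden + 1)
    scaling: Scaling | None = None

    def __post_init__(self) -> None:
        if self.w1.shape != (self.n_hidden, self.n_input + 1):
            raise ValueError("w1 shape inconsistent with layer sizes")
        if self.w2.shape != (self.n_output, self.n_hidden + 1):
            raise ValueError("w2 shape inconsistent with layer sizes")

    def to_json(self) -> str:
        d = {
            "n_input": self.n_input, "n_hidden": self.n_hidden,
            "n_output": self.n_output,
            "w1": self.w1.tolist(), "w2": self.w2.tolist(),
            "scaling": None if self.scaling is None else {
                "x_min": self.scaling.x_min.tolist(),
                "x_max": self.scaling.x_max.tolist(),
                "t_min": self.scaling.t_min, "t_max": self.scaling.t_max,
            },
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetworkModel":
        d = json.loads(s)
        scaling = None
        if d["scaling"] is not None:
            scaling = Scaling(x_min=np.array(d["scaling"]["x_min"]),
                              x_max=np.array(d["scaling"]["x_max"]),
                              t_min=d["scaling"]["t_min"],
                              t_max=d["scaling"]["t_max"])
        return cls(n_input=d["n_input"], n_hidden=d["n_hidden"],
                   n_output=d["n_output"],
                   w1=np.array(d["w1"]), w2=np.array(d["w2"]),
                   scaling=scaling)


@dataclass(frozen=True)
class TrainConfig:
    """Batch-training hyperparameters: 5000 epochs max, initial learning
    rate 0.05, momentum 0.9, scaled-MSE goal 0.001; adaptive-rate constants
    1.05 (grow), 0.7 (shrink), 1.04 (error-inflation acceptance ratio)."""

    max_epochs: int = 5000
    lr0: float = 0.05
    momentum: float = 0.9
    goal: float = 0.001
    lr_up: float = 1.05
    lr_down: float = 0.7
    err_ratio: float = 1.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be nonnegative")


def init_network(n_input: int, n_hidden: int, n_output: int,
                 seed: int) -> NetworkModel:
    """Seeded uniform [-0.5, 0.5] weight initialisation; scaling unset."""
    if min(n_input, n_hidden, n_output) <= 0:
        raise ValueError("layer sizes must be positive")
    rng = np.random.default_rng(seed)
    return NetworkModel(
        n_input=n_input, n_hidden=n_hidden, n_output=n_output,
        w1=rng.uniform(-0.5, 0.5, (n_hidden, n_input + 1)),
        w2=rng.uniform(-0.5, 0.5, (n_output, n_hidden + 1)),
    )


def _forward_batch(model: NetworkModel, X: np.ndarray):
    """Hidden activations U and outputs O for a (n, n_input) batch."""
    Xb = np.hstack([X, np.ones((len(X), 1))])
    U = logsig(Xb @ model.w1.T)  # (n, H)
    Ub = np.hstack([U, np.ones((len(X), 1))])
    O = logsig(Ub @ model.w2.T)  # (n, n_output)
    return Xb, U, Ub, O


def forward(model: NetworkModel, row: Sequence[float]) -> float | np.ndarray:
    """Scaled output for one scaled feature vector (logsig at both layers)."""
    row = np.asarray(row, dtype=float)
    if row.shape != (model.n_input,):
        raise ValueError(
            f"row length {row.shape} does not match n_input {model.n_input}")
    _, _, _, O = _forward_batch(model, row[None, :])
    return float(O[0, 0]) if model.n_output == 1 else O[0]


def mse(model: NetworkModel, X: np.ndarray, T: np.ndarray) -> float:
    _, _, _, O = _forward_batch(model, X)
    return float(np.mean((O - T) ** 2))


def gradients(model: NetworkModel, X: np.ndarray, T: np.ndarray):
    """Analytic batch gradients of the MSE w.r.t. w1 and w2."""
    n = len(X)
    Xb, U, Ub, O = _forward_batch(model, X)
    err = O - T  # (n, n_output)
    e_total = float(np.mean(err**2))
    delta_out = (2.0 / (n * model.n_output)) * err * O * (1.0 - O)
    g2 = delta_out.T @ Ub  # (n_output, H+1)
    delta_hid = (delta_out @ model.w2[:, :model.n_hidden]) * U * (1.0 - U)
    g1 = delta_hid.T @ Xb  # (H, I+1)
    return g1, g2, e_total


def train(model: NetworkModel, rows: np.ndarray, targets: np.ndarray,
          config: TrainConfig) -> tuple[NetworkModel, list[float]]:
    """Batch gradient descent with momentum and adaptive learning rate.

    After each epoch the candidate step is kept (learning rate grown by
    ``lr_up``) unless the error inflated by more than ``err_ratio``, in
    which case the step is discarded, the momentum memory cleared and the
    rate shrunk by ``lr_down``.  Stops at the scaled-MSE goal or at
    ``max_epochs``.  Inputs are expected scaled to [0, 1] and targets to
    [0.1, 0.9]; the ``targets`` may be 1-D for a single output.
    """
    X = np.asarray(rows, dtype=float)
    T = np.asarray(targets, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    w1 = model.w1.copy()
    w2 = model.w2.copy()
    v1 = np.zeros_like(w1)
    v2 = np.zeros_like(w2)
    lr = config.lr0
    cur = replace(model, w1=w1, w2=w2)
    err = mse(cur, X, T)
    history: list[float] = []
    for _ in range(config.max_epochs):
        g1, g2, _ = gradients(cur, X, T)
        if not (np.isfinite(g1).all() and np.isfinite(g2).all()):
            raise FloatingPointError(
                "non-finite gradient encountered during training "
                f"(lr={lr:.3g}, err={err:.3g})")
        v1 = config.momentum * v1 - lr * g1
        v2 = config.momentum * v2 - lr * g2
        cand = replace(cur, w1=cur.w1 + v1, w2=cur.w2 + v2)
        new_err = mse(cand, X, T)
        if new_err > config.err_ratio * err:
            lr *= config.lr_down  # reject the step
            v1[:] = 0.0
            v2[:] = 0.0
        else:
            cur = cand
            err = new_err
            lr *= config.lr_up
        history.append(err)
        if err <= config.goal:
            break
    return cur, history


def fit_bpnn(X: np.ndarray, y: np.ndarray, n_hidden: int,
             config: TrainConfig) -> tuple[NetworkModel, list[float]]:
    """Scale raw features/targets, initialise from the config seed, train."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scaling = Scaling.fit(X, y)
    model = init_network(X.shape[1], n_hidden, 1, config.seed)
    model.scaling = scaling
    trained, history = train(model, scaling.scale_x(X), scaling.scale_t(y),
                             config)
    trained.scaling = scaling
    return trained, history


def predict_ee(model: NetworkModel, rows: np.ndarray) -> np.ndarray:
    """Predict EE (kcal/window) from unscaled 14-feature rows."""
    if model.scaling is None:
        raise ValueError("model is unfitted: no scaling attached")
    X = np.atleast_2d(np.asarray(rows, dtype=float))
    if X.shape[1] != model.n_input:
        raise ValueError(
            f"rows have {X.shape[1]} features, model expects {model.n_input}")
    _, _, _, O = _forward_batch(model, model.scaling.scale_x(X))
    return model.scaling.unscale_t(O[:, 0])


def hidden_node_search(X: np.ndarray, y: np.ndarray,
                       candidates: Sequence[int], config: TrainConfig,
                       val_fraction: float = 0.25
                       ) -> tuple[int, dict[int, float]]:
    """Train one freshly seeded net per hidden-node candidate and score each
    by RMSE (original EE units) on a seeded held-out fold; ties go to the
    smallest candidate."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 hidden-node candidates")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(val_fraction * len(X))))
    val, tr = order[:n_val], order[n_val:]
    rmses: dict[int, float] = {}
    for cand in candidates:
        sub_seed = int(np.random.SeedSequence([config.seed, cand])
                       .generate_state(1)[0] >> 1)
        cand_config = replace(config, seed=sub_seed)
        model, _ = fit_bpnn(X[tr], y[tr], cand, cand_config)
        pred = predict_ee(model, X[val])
        rmses[cand] = float(np.sqrt(np.mean((pred - y[val]) ** 2)))
    return select_best_width(rmses), rmses


def select_best_width(rmses: dict[int, float]) -> int:
    """Candidate with minimal RMSE; ties resolved to the smallest width."""
    return min(sorted(rmses), key=lambda c: rmses[c])
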