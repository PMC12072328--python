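"""Feedforward height/weight regressor and the height→weight estimation path.

The model is a fully connected network 21 → 256 → 128 → 1: two ReLU hidden
layers with dropout (rate 0.1) and a linear output, trained with
mean-squared-error loss and Adam (learning rate 0.001) on mini-batches of
16 for up to 200 epochs, He-normal initialized, with early stopping on
validation loss (patience 20 epochs, best weights restored) after an 80:20
train/validation split.

Inputs and targets are z-scored internally using training-set statistics
(stored in the returned state and inverted at prediction time); on raw
centimeter/kilogram scales an adaptive-gradient step of ~1e-3 per update
could not traverse the ~100-unit output offset within the epoch budget.

The default deployment target is height (cm); the estimated height is then
converted to weight through the growth reference by finding the age whose
median height matches the prediction and reading off the habitus band's
representative weight percentile at that age.  A direct weight-target mode
is also supported.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .growth_reference import (
    BodyType,
    GrowthChart,
    HeightRangeError,
    Sex,
    derive_weight,
    height_to_age_equivalent,
)
from .pose_features import FEATURE_NAMES, N_FEATURES, PoseFrame, SchemaError, build_features

__all__ = [
    "ModelConfig",
    "RegressorState",
    "TrainReport",
    "TrainingError",
    "split_dataset",
    "train",
    "predict",
    "estimate",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingError(RuntimeError):
    """Raised when the loss diverges (becomes non-finite)."""


@dataclass
class ModelConfig:
    hidden_units: tuple[int, int] = (256, 128)
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    split_fraction: float = 0.8
    early_stop_patience: int = 20
    seed: int = 0
    target: str = "height_cm"  # or "weight_kg"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.target not in ("height_cm", "weight_kg"):
            raise ValueError(f"unknown target {self.target!r}")
        for name in ("learning_rate", "epochs", "batch_size", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class RegressorState:
    """Trained parameters plus the input/target scaling frozen at fit time."""

    params: dict[str, np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    config: ModelConfig
    feature_names: tuple[str, ...] = FEATURE_NAMES


@dataclass
class TrainReport:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    stopped_epoch: int
    n_train: int
    n_val: int
    seed: int


def split_dataset(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled disjoint train/validation index split; train size = floor(f·n)."""
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(math.floor(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split of n={n} at fraction={fraction} leaves an empty set")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:]


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------

def init_params(
    n_in: int, hidden: tuple[int, int], seed: int
) -> dict[str, np.ndarray]:
    """He-normal weights (std √(2/fan_in)), zero biases."""
    rng = np.random.default_rng(seed)
    h1, h2 = hidden
    sizes = [(n_in, h1), (h1, h2), (h2, 1)]
    params = {}
    for i, (fan_in, fan_out) in enumerate(sizes, start=1):
        params[f"W{i}"] = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params[f"b{i}"] = np.zeros(fan_out)
    return params


def forward(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass; inverted dropout applied to hidden activations when
    ``dropout_rate`` > 0 (training mode).  Returns (output (n,), cache)."""
    z1 = x @ params["W1"] + params["b1"]
    a1 = np.maximum(z1, 0.0)
    m1 = None
    if dropout_rate > 0.0:
        m1 = (rng.random(a1.shape) >= dropout_rate) / (1.0 - dropout_rate)
        a1 = a1 * m1
    z2 = a1 @ params["W2"] + params["b2"]
    a2 = np.maximum(z2, 0.0)
    m2 = None
    if dropout_rate > 0.0:
        m2 = (rng.random(a2.shape) >= dropout_rate) / (1.0 - dropout_rate)
        a2 = a2 * m2
    out = (a2 @ params["W3"] + params["b3"]).ravel()
    cache = {"x": x, "z1": z1, "a1": a1, "m1": m1, "z2": z2, "a2": a2, "m2": m2}
    return out, cache


def _backward(
    params: dict[str, np.ndarray], cache: dict, grad_out: np.ndarray
) -> dict[str, np.ndarray]:
    g = grad_out[:, None]  # (n, 1) d loss / d output
    grads = {
        "W3": cache["a2"].T @ g,
        "b3": g.sum(axis=0),
    }
    da2 = g @ params["W3"].T
    if cache["m2"] is not None:
        da2 = da2 * cache["m2"]
    dz2 = da2 * (cache["z2"] > 0.0)
    grads["W2"] = cache["a1"].T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    da1 = dz2 @ params["W2"].T
    if cache["m1"] is not None:
        da1 = da1 * cache["m1"]
    dz1 = da1 * (cache["z1"] > 0.0)
    grads["W1"] = cache["x"].T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def train(
    X: np.ndarray, y: np.ndarray, cfg: ModelConfig | None = None
) -> tuple[RegressorState, TrainReport]:
    """Fit the regressor; returns the best-validation-epoch state.

    Deterministic for a fixed config seed on a fixed platform: the split,
    initialization, batch shuffling and dropout masks all derive from it.
    """
    cfg = cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, d) with matching y")
    if len(y) < 10:
        raise ValueError("need at least 10 records to train")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")

    tr_idx, va_idx = split_dataset(len(y), cfg.split_fraction, cfg.seed)
    x_mean = X[tr_idx].mean(axis=0)
    x_std = np.maximum(X[tr_idx].std(axis=0), 1e-8)
    y_mean = float(y[tr_idx].mean())
    y_std = float(max(y[tr_idx].std(), 1e-8))
    Xs = (X - x_mean) / x_std
    ys = (y - y_mean) / y_std
    Xtr, ytr = Xs[tr_idx], ys[tr_idx]
    Xva, yva = Xs[va_idx], ys[va_idx]

    rng = np.random.default_rng(cfg.seed + 1)
    params = init_params(X.shape[1], cfg.hidden_units, cfg.seed + 2)
    opt = _Adam(params, cfg.learning_rate)

    best_val = np.inf
    best_epoch = -1
    best_params = {k: v.copy() for k, v in params.items()}
    train_losses: list[float] = []
    val_losses: list[float] = []
    since_best = 0
    stopped = cfg.epochs - 1

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ytr))
        epoch_loss = 0.0
        for start in range(0, len(ytr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            out, cache = forward(params, xb, cfg.dropout_rate, rng)
            resid = out - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            grads = _backward(params, cache, 2.0 * resid / len(yb))
            opt.step(params, grads)
            epoch_loss += loss * len(yb)
        train_losses.append(epoch_loss / len(ytr))

        val_out, _ = forward(params, Xva)
        val_loss = float(np.mean((val_out - yva) ** 2))
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        val_losses.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                stopped = epoch
                break
        stopped = epoch

    state = RegressorState(
        params=best_params,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        config=cfg,
    )
    report = TrainReport(
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best_epoch,
        stopped_epoch=stopped,
        n_train=len(tr_idx),
        n_val=len(va_idx),
        seed=cfg.seed,
    )
    return state, report


def predict(state: RegressorState, features: np.ndarray) -> float | np.ndarray:
    """Deterministic inference (dropout off); accepts a vector or a matrix."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != len(state.x_mean):
        raise SchemaError(
            f"feature length {x.shape[1]} != expected {len(state.x_mean)}"
        )
    xs = (x - state.x_mean) / state.x_std
    out, _ = forward(state.params, xs)
    y = out * state.y_std + state.y_mean
    return float(y[0]) if single else y


def estimate(
    state: RegressorState,
    frame: PoseFrame,
    sex: Sex | str,
    age_months: float,
    body_type: BodyType | str,
    chart: GrowthChart,
    out_of_range: str = "raise",
) -> tuple[float, float]:
    """Full estimation path: pose frame + metadata → (height cm, weight kg).

    Height-target mode predicts height then maps it to weight through the
    growth reference (median-height age equivalent → habitus-band weight).
    Direct mode predicts weight and reports the chart-implied height for the
    subject's age.  ``out_of_range``: "raise" surfaces a predicted height
    outside the chart's median curve as :class:`HeightRangeError` with the
    raw prediction attached; "clamp" pins it to the nearest curve endpoint.
    """
    if out_of_range not in ("raise", "clamp"):
        raise ValueError("out_of_range must be 'raise' or 'clamp'")
    feats = build_features(frame, sex, age_months, body_type)
    pred = predict(state, feats)

    if state.config.target == "weight_kg":
        from .growth_reference import percentile_height

        return percentile_height(chart, sex, age_months, 0.5), float(pred)

    height = float(pred)
    sub = chart._by_sex[Sex(sex).value]
    lo = float(sub["height_median_cm"].iloc[0])
    hi = float(sub["height_median_cm"].iloc[-1])
    if not lo <= height <= hi:
        if out_of_range == "raise":
            err = HeightRangeError(
                f"predicted height {height:.2f} cm outside chart median range "
                f"[{lo:.2f}, {hi:.2f}]"
            )
            err.raw_prediction = height
            raise err
        height = min(max(height, lo), hi)
    age_eq = height_to_age_equivalent(chart, sex, height)
    weight = derive_weight(chart, sex, age_eq, body_type)
    return height, weight


# ---------------------------------------------------------------------------
# Checkpoint I/O (portable JSON: config echo, scaling, weights, column order)
# ---------------------------------------------------------------------------

def save_checkpoint(state: RegressorState, path) -> None:
    payload = {
        "config": asdict(state.config),
        "feature_names": list(state.feature_names),
        "x_mean": state.x_mean.tolist(),
        "x_std": state.x_std.tolist(),
        "y_mean": state.y_mean,
        "y_std": state.y_std,
        "params": {k: v.tolist() for k, v in state.params.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> RegressorState:
    payload = json.loads(Path(path).read_text())
    names = tuple(payload["feature_names"])
    if names != FEATURE_NAMES:
        raise SchemaError("checkpoint feature column order does not match this build")
    cfgd = payload["config"]
    cfgd["hidden_units"] = tuple(cfgd["hidden_units"])
    return RegressorState(
        params={k: np.asarray(v) for k, v in payload["params"].items()},
        x_mean=np.asarray(payload["x_mean"]),
        x_std=np.asarray(payload["x_std"]),
        y_mean=float(payload["y_mean"]),
        y_std=float(payload["y_std"]),
        config=ModelConfig(**cfgd),
        feature_names=names,
    )
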