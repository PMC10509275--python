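"""Fully connected networks for scratch intensity and scratch detection.

Two fixed architectures, trained on normalized spectral features:

* intensity regression: 575 -> 1000 -> 1000 -> 1 (ReLU hidden layers,
  linear output), dropout p = 0.1 on each hidden layer, mean-absolute-
  error loss, Adam at 5e-6, batch 64, 150 epochs;
* scratch detection: 475 -> 1200 -> 1200 -> 1200 -> 1 (ReLU hidden
  layers, sigmoid output), dropout p = 0.2, binary cross-entropy loss,
  Adam at 1e-5, batch 64, 150 epochs.

The implementation is a compact seeded NumPy MLP (He-normal init,
inverted dropout, per-epoch shuffling, Adam); given the same data and
seed, training and prediction are bit-reproducible on one machine.
Smaller epoch/learning-rate combinations can be configured for reduced
problem sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import expit

from .wearable_features import ScalerParams, TASK_BINS


class ModelError(ValueError):
    pass


def reduced_config(task: str):
    """Training recipe scaled for small synthetic cohorts.

    The study architectures are kept; epochs are cut and the Adam step
    enlarged in proportion, since at the full-recipe learning rate the
    parameter displacement after a few epochs on a few thousand samples
    is negligible.
    """
    if task == "intensity":
        return IntensityModelConfig(learning_rate=1e-3, epochs=10)
    if task == "detection":
        return DetectionModelConfig(learning_rate=1e-3, epochs=1)
    raise ModelError(f"unknown task {task!r}")


@dataclass
class IntensityModelConfig:
    """Training recipe for the intensity regressor."""

    hidden_layers: int = 2
    hidden_size: int = 1000
    dropout_p: float = 0.1
    learning_rate: float = 5e-6
    loss: str = "mae"
    batch_size: int = 64
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        _check_config(self)


@dataclass
class DetectionModelConfig:
    """Training recipe for the scratch detector (sigmoid output)."""

    hidden_layers: int = 3
    hidden_size: int = 1200
    dropout_p: float = 0.2
    learning_rate: float = 1e-5
    loss: str = "bce"
    batch_size: int = 64
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        _check_config(self)


def _check_config(cfg) -> None:
    if cfg.hidden_layers < 1 or cfg.hidden_size < 1:
        raise ModelError("network must have positive depth and width")
    if not (0.0 <= cfg.dropout_p < 1.0):
        raise ModelError("dropout_p must be in [0, 1)")
    if cfg.learning_rate <= 0 or cfg.batch_size < 1 or cfg.epochs < 1:
        raise ModelError("learning_rate, batch_size and epochs must be positive")


@dataclass
class TrainedModel:
    """Weights plus the provenance needed to apply them safely."""

    weights: List[np.ndarray]
    biases: List[np.ndarray]
    config: object
    task: str
    input_dim: int
    scaler: Optional[ScalerParams] = None
    loss_curve: np.ndarray = field(default_factory=lambda: np.empty(0))


def _init_params(dims: List[int], rng: np.random.Generator):
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(
            rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)
        )
        biases.append(np.zeros(d_out, dtype=np.float32))
    return weights, biases


def _forward(X, weights, biases, dropout_p=0.0, rng=None):
    """Forward pass; returns pre-output activation list for backprop."""
    acts = [X]
    h = X
    for i, (W, b) in enumerate(zip(weights[:-1], biases[:-1])):
        h = np.maximum(h @ W + b, 0.0)
        if dropout_p > 0.0 and rng is not None:
            keep = (rng.random(h.shape) >= dropout_p).astype(np.float32)
            h = h * keep / np.float32(1.0 - dropout_p)
        acts.append(h)
    out = h @ weights[-1] + biases[-1]
    return out[:, 0], acts


def _train(X, y, dims, cfg, sigmoid_out: bool) -> Tuple[list, list, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(dims, rng)
    mW = [np.zeros_like(w) for w in weights]
    vW = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = np.float32(cfg.learning_rate)
    step = 0
    n = X.shape[0]
    losses = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            out, acts = _forward(xb, weights, biases, cfg.dropout_p, rng)
            m = xb.shape[0]
            if sigmoid_out:
                p = expit(out)
                pc = np.clip(p, 1e-7, 1.0 - 1e-7)
                epoch_loss += float(
                    -np.sum(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))
                )
                grad_out = (p - yb) / m  # BCE through the sigmoid
            else:
                err = out - yb
                epoch_loss += float(np.abs(err).sum())
                grad_out = np.sign(err) / m  # MAE subgradient
            # backprop
            delta = grad_out[:, None].astype(np.float32)
            grads_W, grads_b = [None] * len(weights), [None] * len(biases)
            for li in range(len(weights) - 1, -1, -1):
                grads_W[li] = acts[li].T @ delta
                grads_b[li] = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ weights[li].T) * (acts[li] > 0)
            # Adam
            step += 1
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            for li in range(len(weights)):
                mW[li] = b1 * mW[li] + (1 - b1) * grads_W[li]
                vW[li] = b2 * vW[li] + (1 - b2) * grads_W[li] ** 2
                weights[li] -= lr * (mW[li] / corr1) / (np.sqrt(vW[li] / corr2) + eps)
                mb[li] = b1 * mb[li] + (1 - b1) * grads_b[li]
                vb[li] = b2 * vb[li] + (1 - b2) * grads_b[li] ** 2
                biases[li] -= lr * (mb[li] / corr1) / (np.sqrt(vb[li] / corr2) + eps)
        losses[epoch] = epoch_loss / n
    return weights, biases, losses


def _prepare(X, y, expected_dim: Optional[int]) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2:
        raise ModelError("feature matrix must be 2-D")
    if X.shape[0] == 0:
        raise ModelError("empty training set")
    if expected_dim is not None and X.shape[1] != expected_dim:
        raise ModelError(f"expected {expected_dim} features, got {X.shape[1]}")
    y = np.asarray(y, dtype=np.float32)
    if y.shape != (X.shape[0],):
        raise ModelError("labels must be 1-D and match the feature rows")
    return X, y


def train_intensity(
    features: np.ndarray,
    power_labels_mw: np.ndarray,
    config: Optional[IntensityModelConfig] = None,
    seed: Optional[int] = None,
    scaler: Optional[ScalerParams] = None,
) -> TrainedModel:
    """Train the intensity regressor on normalized features (labels in mW)."""
    cfg = config or IntensityModelConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    X, y = _prepare(features, power_labels_mw, None)
    dims = [X.shape[1]] + [cfg.hidden_size] * cfg.hidden_layers + [1]
    weights, biases, losses = _train(X, y, dims, cfg, sigmoid_out=False)
    return TrainedModel(weights, biases, cfg, "intensity", X.shape[1], scaler, losses)


def predict_intensity(model: TrainedModel, features: np.ndarray, clip: bool = False) -> np.ndarray:
    """Predict scratch power in mW; optionally clip onto the 0-600 scale."""
    X = np.asarray(features, dtype=np.float32)
    X = np.atleast_2d(X)
    if X.shape[1] != model.input_dim:
        raise ModelError(f"expected {model.input_dim} features, got {X.shape[1]}")
    out, _ = _forward(X, model.weights, model.biases)
    out = out.astype(float)
    if clip:
        out = np.clip(out, 0.0, 600.0)
    return out


def train_detection(
    features: np.ndarray,
    binary_labels: np.ndarray,
    config: Optional[DetectionModelConfig] = None,
    seed: Optional[int] = None,
    scaler: Optional[ScalerParams] = None,
) -> TrainedModel:
    """Train the scratch detector on normalized features (labels 0/1)."""
    import logging

    cfg = config or DetectionModelConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    X, y = _prepare(features, binary_labels, None)
    if np.unique(y).size < 2:
        logging.getLogger(__name__).warning(
            "detection training set contains a single class"
        )
    dims = [X.shape[1]] + [cfg.hidden_size] * cfg.hidden_layers + [1]
    weights, biases, losses = _train(X, y, dims, cfg, sigmoid_out=True)
    return TrainedModel(weights, biases, cfg, "detection", X.shape[1], scaler, losses)


def predict_scratch(
    model: TrainedModel, features: np.ndarray, threshold: float = 0.5
) -> Tuple[np.ndarray, np.ndarray]:
    """Scratch probability and binary call (ties at threshold -> positive)."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float32))
    if X.shape[1] != model.input_dim:
        raise ModelError(f"expected {model.input_dim} features, got {X.shape[1]}")
    out, _ = _forward(X, model.weights, model.biases)
    prob = expit(out.astype(float))
    return prob, prob >= threshold


def save_model(model: TrainedModel, path) -> None:
    """Serialize weights + config + scaler to a portable .npz archive."""
    cfg = dataclasses.asdict(model.config)
    meta = {"task": model.task, "input_dim": model.input_dim, "config": cfg}
    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    arrays["loss_curve"] = model.loss_curve
    if model.scaler is not None:
        arrays["scaler_min"] = model.scaler.minimum
        arrays["scaler_max"] = model.scaler.maximum
        meta["scaler_fitted_on"] = model.scaler.fitted_on
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        weights = [data[f"W{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
        scaler = None
        if "scaler_min" in data.files:
            scaler = ScalerParams(
                data["scaler_min"], data["scaler_max"],
                fitted_on=meta.get("scaler_fitted_on", ""),
            )
        cfg_cls = IntensityModelConfig if meta["task"] == "intensity" else DetectionModelConfig
        return TrainedModel(
            weights, biases, cfg_cls(**meta["config"]), meta["task"],
            meta["input_dim"], scaler, data["loss_curve"],
        )
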