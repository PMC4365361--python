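"""Confidence-aware feed-forward screener.

A single-hidden-layer network maps the 18 DoC-pipeline features (normalized
interval extremes plus per-attribute DoC for each of the six record
attributes) to two logistic outputs: the chance the record indicates
schizophrenia, and the confidence one may place in that answer.  The
confidence output is trained against the record's clause DoC, so the
network learns to report *less* confidence for records encoded from more
degraded data.

Training is full-batch Adam on a joint loss — binary cross-entropy for the
class output, squared error for the confidence output — with early stopping
on a held-out validation split.  All randomness (weight initialisation,
validation shuffle) derives from the config seed, so identical data and
config reproduce identical weights.  Models serialize to a single JSON file
including their provenance (config, seed, SHA-256 of the training arrays).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["NetworkConfig", "TrainedModel", "Prediction", "train", "predict", "evaluate"]

N_INPUTS = 18
N_OUTPUTS = 2  # (p_schizophrenia, confidence)


@dataclass(frozen=True)
class NetworkConfig:
    hidden_units: int = 8
    max_epochs: int = 800
    learning_rate: float = 0.02
    validation_fraction: float = 0.1
    patience: int = 50  # early-stopping patience, in epochs
    checkpoint_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class Prediction:
    p_schizophrenia: float
    confidence: float


@dataclass
class TrainedModel:
    """Weights of the 18-h-2 logistic network plus training provenance."""

    w1: np.ndarray  # (hidden, 18)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (2, hidden)
    b2: np.ndarray  # (2,)
    config: NetworkConfig
    data_hash: str = ""
    loss_checkpoints: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        h = self.config.hidden_units
        if self.w1.shape != (h, N_INPUTS) or self.b1.shape != (h,):
            raise ValueError("input->hidden shapes inconsistent with config")
        if self.w2.shape != (N_OUTPUTS, h) or self.b2.shape != (N_OUTPUTS,):
            raise ValueError("hidden->output shapes inconsistent with config")

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "config": asdict(self.config),
            "data_hash": self.data_hash,
            "loss_checkpoints": self.loss_checkpoints,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @staticmethod
    def from_json(path) -> "TrainedModel":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return TrainedModel(
            w1=np.asarray(obj["w1"]),
            b1=np.asarray(obj["b1"]),
            w2=np.asarray(obj["w2"]),
            b2=np.asarray(obj["b2"]),
            config=NetworkConfig(**obj["config"]),
            data_hash=obj["data_hash"],
            loss_checkpoints=list(obj["loss_checkpoints"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(m_w1, m_b1, m_w2, m_b2, x: np.ndarray):
    h = _sigmoid(x @ m_w1.T + m_b1)
    o = _sigmoid(h @ m_w2.T + m_b2)
    return h, o


def _loss(o: np.ndarray, y: np.ndarray, c: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(o[:, 0], eps, 1 - eps)
    bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    mse = (o[:, 1] - c) ** 2
    return float(np.mean(bce + mse))


def train(
    features: np.ndarray,
    labels: Sequence[int],
    confidences: Sequence[float],
    cfg: NetworkConfig = NetworkConfig(),
) -> TrainedModel:
    """Fit the screener on encoded cases.

    ``confidences`` are the clause DoCs of the corresponding feature
    vectors; they become the regression target of the second output.
    Requires both classes to be present and finite features.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    c = np.asarray(confidences, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_INPUTS:
        raise ValueError(f"features must be (n, {N_INPUTS})")
    if not (len(x) == len(y) == len(c)) or len(x) == 0:
        raise ValueError("features, labels and confidences must be non-empty and equal-length")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain NaN or infinite entries")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(x))
    n_val = max(1, int(round(cfg.validation_fraction * len(x))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xt, yt, ct = x[tr_idx], y[tr_idx], c[tr_idx]
    xv, yv, cv = x[val_idx], y[val_idx], c[val_idx]

    h = cfg.hidden_units
    # Glorot-style small init, seeded
    w1 = rng.normal(0.0, np.sqrt(2.0 / (N_INPUTS + h)), size=(h, N_INPUTS))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(2.0 / (h + N_OUTPUTS)), size=(N_OUTPUTS, h))
    b2 = np.zeros(N_OUTPUTS)

    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_train = np.inf
    since_best = 0
    checkpoints: list[float] = []
    n = len(xt)

    for epoch in range(1, cfg.max_epochs + 1):
        hid, out = _forward(w1, b1, w2, b2, xt)
        # output deltas: BCE+sigmoid for class, MSE+sigmoid for confidence
        d_out = np.empty_like(out)
        d_out[:, 0] = out[:, 0] - yt
        d_out[:, 1] = 2.0 * (out[:, 1] - ct) * out[:, 1] * (1.0 - out[:, 1])
        d_out /= n
        g_w2 = d_out.T @ hid
        g_b2 = d_out.sum(axis=0)
        d_hid = (d_out @ w2) * hid * (1.0 - hid)
        g_w1 = d_hid.T @ xt
        g_b1 = d_hid.sum(axis=0)

        for p, g, mi, vi in zip(params, [g_w1, g_b1, g_w2, g_b2], m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g * g
            mhat = mi / (1 - beta1**epoch)
            vhat = vi / (1 - beta2**epoch)
            p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        _, out_tr = _forward(w1, b1, w2, b2, xt)
        train_loss = _loss(out_tr, yt, ct)
        best_train = min(best_train, train_loss)
        if epoch % cfg.checkpoint_every == 0:
            checkpoints.append(best_train)  # best-so-far, hence non-increasing

        _, out_val = _forward(w1, b1, w2, b2, xv)
        val_loss = _loss(out_val, yv, cv)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    w1, b1, w2, b2 = best_params
    digest = hashlib.sha256()
    for arr in (x, y, c):
        digest.update(np.ascontiguousarray(arr).tobytes())
    return TrainedModel(
        w1=w1, b1=b1, w2=w2, b2=b2, config=cfg,
        data_hash=digest.hexdigest(), loss_checkpoints=checkpoints,
    )


def predict(m: TrainedModel, f: np.ndarray) -> Prediction:
    """Forward pass for one feature vector; both outputs are logistic."""
    f = np.asarray(f, dtype=float)
    if f.shape != (N_INPUTS,):
        raise ValueError(f"feature vector must have shape ({N_INPUTS},), got {f.shape}")
    _, o = _forward(m.w1, m.b1, m.w2, m.b2, f[None, :])
    return Prediction(float(o[0, 0]), float(o[0, 1]))


def predict_batch(m: TrainedModel, features: np.ndarray) -> np.ndarray:
    """(n, 2) array of (p_schizophrenia, confidence) rows."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_INPUTS:
        raise ValueError(f"features must be (n, {N_INPUTS})")
    _, o = _forward(m.w1, m.b1, m.w2, m.b2, x)
    return o


def evaluate(m: TrainedModel, features: np.ndarray, labels: Sequence[int]) -> dict:
    """Accuracy, sensitivity, specificity and mean confidence at threshold 0.5."""
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty set")
    o = predict_batch(m, features)
    pred = (o[:, 0] >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {
        "n": len(y),
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "mean_confidence": float(np.mean(o[:, 1])),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
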