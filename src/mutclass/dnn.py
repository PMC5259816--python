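"""From-scratch fully connected classifier.

The network is a plain multilayer perceptron: each hidden layer computes
``x_{l+1} = ReLU(W_l x_l + b_l)``, the final layer emits raw logits
``x_L`` (no rectifier — clipping negative evidence before the softmax
would discard information), and class probabilities come from a
numerically stabilized softmax ``P_i = exp(x_L(i)) / Σ_j exp(x_L(j))``.
Training minimizes the logarithmic loss ``J = −Σ_i y_i log P_i`` plus an
L2 weight-decay penalty by mini-batch stochastic gradient descent with
analytically derived backpropagation.  The per-epoch learning rate comes
from a schedule (by default 50 log-spaced points from 1e-1 down to 1e-4,
one per epoch), decay applies to weights only, the sample order is
reshuffled every epoch under a fixed seed, and the last incomplete batch
is trained rather than dropped — the whole trajectory is deterministic
given the seed.

Weights are initialized from a zero-mean Gaussian with variance 2/fan-in
(the rectifier-appropriate scaling; wide layers do not train from naive
unit-variance draws), biases at zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = 1e-12  # clamp for log loss when the true-class probability underflows


class TrainingDivergedError(RuntimeError):
    """Loss became NaN/inf during training (learning rate too high?)."""


@dataclass
class NetworkConfig:
    """Architecture: input width, hidden layer count and width, number of
    cancer types.  Defaults follow the reference configuration: 4 hidden
    layers of 8192 units and 12 output classes."""

    input_dim: int
    output_dim: int = 12
    hidden_layers: int = 4
    units_per_layer: int = 8192

    def __post_init__(self) -> None:
        if min(self.input_dim, self.output_dim, self.units_per_layer) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")

    def layer_dims(self) -> list[int]:
        return [self.input_dim] + [self.units_per_layer] * self.hidden_layers + [
            self.output_dim
        ]


def default_lr_schedule(max_epochs: int = 50) -> np.ndarray:
    """Log-spaced learning rates from 1e-1 to 1e-4, one per epoch."""
    return np.logspace(-1, -4, max_epochs)


@dataclass
class TrainConfig:
    """Mini-batch SGD schedule: 50 epochs, log-spaced learning rate
    1e-1 → 1e-4, weight decay 5e-4, batch size 256."""

    max_epochs: int = 50
    lr_schedule: np.ndarray | None = None
    weight_decay: float = 5e-4
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_schedule is None:
            self.lr_schedule = default_lr_schedule(self.max_epochs)
        self.lr_schedule = np.asarray(self.lr_schedule, dtype=np.float64)
        if len(self.lr_schedule) < self.max_epochs:
            raise ValueError("lr_schedule must provide one rate per epoch")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("invalid batch_size/max_epochs")


@dataclass
class NetworkParams:
    """Per-layer weight matrices ``W_l`` (out × in) and bias vectors ``b_l``."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights],
                             [b.copy() for b in self.biases])


@dataclass
class PredictionResult:
    """Softmax probabilities, 1-based argmax class, and (optionally) the
    log loss against a known label."""

    probabilities: np.ndarray
    predicted_class: int
    loss: float | None = None


def init_params(cfg: NetworkConfig, rng: np.random.Generator) -> NetworkParams:
    dims = cfg.layer_dims()
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in))
        biases.append(np.zeros(d_out))
    return NetworkParams(weights, biases)


def forward(x: np.ndarray, params: NetworkParams) -> tuple[list[np.ndarray], np.ndarray]:
    """Feed-forward pass; accepts a single sample (d,) or a batch (n, d).

    Returns the list of layer inputs (activations; index 0 is the input
    itself) and the output-layer logits ``x_L``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != params.weights[0].shape[1]:
        raise ValueError(
            f"input width {x.shape[1]} != expected {params.weights[0].shape[1]}"
        )
    activations = [x]
    n_layers = len(params.weights)
    for l, (w, b) in enumerate(zip(params.weights, params.biases)):
        z = activations[-1] @ w.T + b
        if l < n_layers - 1:
            activations.append(np.maximum(z, 0.0))  # ReLU on hidden layers
        else:
            logits = z  # raw logits feed the softmax
    return activations, logits


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max subtraction (shift-invariant)."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_loss(probs: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean logarithmic loss ``J = −Σ_i y_i log P_i`` over a batch.

    True-class probabilities below 1e-12 are clamped (and logged) so the
    loss stays finite.
    """
    probs = np.atleast_2d(probs)
    y_onehot = np.atleast_2d(y_onehot)
    p_true = (probs * y_onehot).sum(axis=1)
    if (p_true < _EPS).any():
        logger.warning("clamping %d true-class probabilities below %g",
                       int((p_true < _EPS).sum()), _EPS)
        p_true = np.maximum(p_true, _EPS)
    return float(-np.log(p_true).mean())


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Labels 1..K to one-hot rows."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(f"labels must lie in 1..{n_classes}")
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


def backward(
    x: np.ndarray,
    y_onehot: np.ndarray,
    params: NetworkParams,
    weight_decay: float = 0.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the mean log loss (+ L2 penalty on weights) w.r.t.
    every ``W_l`` and ``b_l``.

    Uses the closed form ``∂J/∂logits = P − y``; the decay term adds
    ``weight_decay · W_l`` to each weight gradient and never touches the
    biases.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y_onehot = np.atleast_2d(y_onehot)
    activations, logits = forward(x, params)
    n = x.shape[0]
    delta = (softmax(logits) - y_onehot) / n
    grads_w: list[np.ndarray] = [None] * len(params.weights)
    grads_b: list[np.ndarray] = [None] * len(params.weights)
    for l in range(len(params.weights) - 1, -1, -1):
        grads_w[l] = delta.T @ activations[l] + weight_decay * params.weights[l]
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ params.weights[l]) * (activations[l] > 0)
    return grads_w, grads_b


def train(
    features: np.ndarray,
    labels: np.ndarray,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> tuple[NetworkParams, list[float]]:
    """Mini-batch SGD training; returns final parameters and the
    per-epoch mean training-loss trajectory."""
    features = np.asarray(features, dtype=np.float64)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    y = one_hot(labels, net_cfg.output_dim)
    rng = np.random.default_rng(train_cfg.seed)
    params = init_params(net_cfg, rng)
    n = features.shape[0]
    history: list[float] = []
    for epoch in range(train_cfg.max_epochs):
        lr = float(train_cfg.lr_schedule[epoch])
        perm = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            batch = perm[start: start + train_cfg.batch_size]
            xb, yb = features[batch], y[batch]
            _, logits = forward(xb, params)
            loss = log_loss(softmax(logits), yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}; lower the learning rate"
                )
            grads_w, grads_b = backward(xb, yb, params, train_cfg.weight_decay)
            for l in range(len(params.weights)):
                params.weights[l] -= lr * grads_w[l]
                params.biases[l] -= lr * grads_b[l]
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
        logger.debug("epoch %d: lr=%.3g loss=%.4f", epoch + 1, lr, history[-1])
    return params, history


def predict(x: np.ndarray, params: NetworkParams) -> PredictionResult:
    """Classify one sample; ties broken toward the lowest class index."""
    _, logits = forward(x, params)
    probs = softmax(logits)[0]
    return PredictionResult(probabilities=probs,
                            predicted_class=int(np.argmax(probs)) + 1)


def predict_batch(x: np.ndarray, params: NetworkParams) -> np.ndarray:
    """1-based predicted classes for a batch (n, d)."""
    _, logits = forward(x, params)
    return np.argmax(softmax(logits), axis=1) + 1


class DnnClassifier:
    """Thin fit/predict wrapper so the pipeline can swap classifiers."""

    def __init__(self, net_cfg: NetworkConfig | None = None,
                 train_cfg: TrainConfig | None = None):
        self.net_cfg = net_cfg
        self.train_cfg = train_cfg or TrainConfig()
        self.params: NetworkParams | None = None
        self.history: list[float] = []

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "DnnClassifier":
        cfg = self.net_cfg
        if cfg is None or cfg.input_dim != features.shape[1]:
            base = cfg or NetworkConfig(input_dim=1)
            cfg = NetworkConfig(
                input_dim=features.shape[1],
                output_dim=base.output_dim,
                hidden_layers=base.hidden_layers,
                units_per_layer=base.units_per_layer,
            )
        self._fitted_cfg = cfg
        self.params, self.history = train(features, labels, cfg, self.train_cfg)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        return predict_batch(features, self.params)


def save_checkpoint(path, params: NetworkParams, meta: dict) -> None:
    """Single-file model checkpoint: all W_l/b_l plus a JSON metadata
    blob (architecture, featurizer state) needed to score new samples."""
    arrays = {f"W{l}": w for l, w in enumerate(params.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(params.biases)})
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> tuple[NetworkParams, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        params = NetworkParams(
            weights=[data[f"W{l}"] for l in range(n_layers)],
            biases=[data[f"b{l}"] for l in range(n_layers)],
        )
    return params, meta
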