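"""Feed-forward classifier for detection-level and bin-level inputs.

One architecture serves both input types: four fully connected hidden
layers of 512 units with leaky-ReLU activations, 50% dropout between
layers, and a softmax output over the signal classes. Training minimizes
cross-entropy with an RMSprop optimizer at a constant learning rate
(default 3e-4), mini-batches of 2000 detections or 100 bins, and early
stopping: when validation loss has not improved for ``patience`` (default
3) consecutive epochs, training stops and the best-validation-epoch
weights are restored. At most 15 epochs are run.

Implemented directly on numpy: forward/backward passes, dropout masks and
the optimizer state are explicit, which keeps training deterministic
under a fixed seed and dependency-free on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ModelSpec:
    input_dim: int
    n_classes: int
    hidden: tuple[int, ...] = (512, 512, 512, 512)
    dropout: float = 0.5
    leaky_slope: float = 0.01


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 2000  # 100 for bin-level inputs
    patience: int = 3
    max_epochs: int = 15
    rms_decay: float = 0.9
    rms_eps: float = 1e-8
    monitor: str = "val_loss"  # or "val_accuracy"
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.patience, self.max_epochs) <= 0:
            raise ValueError("all TrainConfig numeric fields must be positive")


@dataclass
class TrainedModel:
    spec: ModelSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    class_names: list[str] = field(default_factory=list)


@dataclass
class PredictionSet:
    probabilities: np.ndarray  # (n, n_classes), rows sum to 1

    @property
    def labels(self) -> np.ndarray:
        return self.probabilities.argmax(axis=1)

    @property
    def scores(self) -> np.ndarray:
        """Maximum class probability per item — the confidence score."""
        return self.probabilities.max(axis=1)


def _init_params(spec: ModelSpec, rng: np.random.Generator):
    dims = [spec.input_dim, *spec.hidden, spec.n_classes]
    weights = [
        (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        for d_in, d_out in zip(dims[:-1], dims[1:])
    ]
    biases = [np.zeros(d, dtype=np.float32) for d in dims[1:]]
    return weights, biases


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: TrainedModel, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
    """Returns (probabilities, cache for backprop). Dropout only when rng given."""
    spec = model.spec
    a = X.astype(np.float32)
    cache = []
    n_hidden = len(spec.hidden)
    for layer, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        if layer < n_hidden:
            act = np.where(z > 0, z, spec.leaky_slope * z)
            if dropout_rng is not None and spec.dropout > 0:
                mask = (dropout_rng.random(act.shape) >= spec.dropout) / (1 - spec.dropout)
                act = act * mask.astype(np.float32)
            else:
                mask = None
            cache.append((a, z, mask))
            a = act
        else:
            cache.append((a, z, None))
            a = _softmax(z)
    return a, cache


def _backward(model: TrainedModel, cache, probs: np.ndarray, y_onehot: np.ndarray):
    spec = model.spec
    n = len(probs)
    grads_w, grads_b = [], []
    delta = (probs - y_onehot).astype(np.float32) / n
    for layer in range(len(model.weights) - 1, -1, -1):
        a_in, z, mask = cache[layer]
        grads_w.append(a_in.T @ delta)
        grads_b.append(delta.sum(axis=0))
        if layer > 0:
            da = delta @ model.weights[layer].T
            _, prev_z, prev_mask = cache[layer - 1]
            if prev_mask is not None:
                da = da * prev_mask
            delta = da * np.where(prev_z > 0, 1.0, spec.leaky_slope).astype(np.float32)
    return grads_w[::-1], grads_b[::-1]


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).mean())


def evaluate(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(cross-entropy loss, accuracy) with dropout disabled."""
    probs, _ = _forward(model, X)
    return _cross_entropy(probs, y), float((probs.argmax(axis=1) == y).mean())


def train(
    spec: ModelSpec,
    cfg: TrainConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    class_names: list[str] | None = None,
) -> tuple[TrainedModel, list[dict]]:
    """Mini-batch RMSprop training with patience-based early stopping.

    Validation is evaluated after every epoch; training stops when the
    monitored metric has not improved for ``patience`` consecutive epochs
    (or at ``max_epochs``), and the best epoch's weights are restored.
    Returns (model, history) where history has one dict per epoch run.
    """
    if X_train.shape[1] != spec.input_dim:
        raise ValueError(f"input_dim mismatch: spec {spec.input_dim}, data {X_train.shape[1]}")
    if len(X_val) == 0:
        raise ValueError("validation set must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(spec, rng)
    model = TrainedModel(spec, weights, biases, class_names or [])
    sq_w = [np.zeros_like(w) for w in weights]
    sq_b = [np.zeros_like(b) for b in biases]
    onehot = np.eye(spec.n_classes, dtype=np.float32)

    history: list[dict] = []
    best_metric = np.inf
    best_weights = None
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(X_train))
        tr_loss_sum, tr_correct = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            Xb, yb = X_train[sel], y_train[sel]
            probs, cache = _forward(model, Xb, dropout_rng=rng)
            if not np.isfinite(probs).all():
                raise FloatingPointError(f"non-finite activations at epoch {epoch}")
            gw, gb = _backward(model, cache, probs, onehot[yb])
            for i in range(len(model.weights)):
                sq_w[i] = cfg.rms_decay * sq_w[i] + (1 - cfg.rms_decay) * gw[i] ** 2
                sq_b[i] = cfg.rms_decay * sq_b[i] + (1 - cfg.rms_decay) * gb[i] ** 2
                model.weights[i] -= cfg.learning_rate * gw[i] / (np.sqrt(sq_w[i]) + cfg.rms_eps)
                model.biases[i] -= cfg.learning_rate * gb[i] / (np.sqrt(sq_b[i]) + cfg.rms_eps)
            tr_loss_sum += _cross_entropy(probs, yb) * len(sel)
            tr_correct += int((probs.argmax(axis=1) == yb).sum())
        val_loss, val_acc = evaluate(model, X_val, y_val)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"NaN validation loss at epoch {epoch}")
        history.append(
            {
                "epoch": epoch,
                "train_loss": tr_loss_sum / len(order),
                "train_accuracy": tr_correct / len(order),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        metric = val_loss if cfg.monitor == "val_loss" else -val_acc
        if metric < best_metric:
            best_metric = metric
            best_weights = ([w.copy() for w in model.weights], [b.copy() for b in model.biases])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_weights is not None:
        model.weights, model.biases = best_weights
    return model, history


def predict(model: TrainedModel, X: np.ndarray) -> PredictionSet:
    """Deterministic inference (dropout disabled); rows sum to 1."""
    probs, _ = _forward(model, np.asarray(X))
    return PredictionSet(probabilities=probs)


def apply_threshold(preds: PredictionSet, tau: float) -> np.ndarray:
    """Argmax labels where the confidence score ≥ tau, else −1 (discarded)."""
    return np.where(preds.scores >= tau, preds.labels, -1)


def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    header = {
        "format_version": 1,
        "input_dim": model.spec.input_dim,
        "n_classes": model.spec.n_classes,
        "hidden": list(model.spec.hidden),
        "dropout": model.spec.dropout,
        "leaky_slope": model.spec.leaky_slope,
        "class_names": model.class_names,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path, header=json.dumps(header), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        n_layers = len(header["hidden"]) + 1
        weights = [data[f"w{i}"] for i in range(n_layers)]
        biases = [data[f"b{i}"] for i in range(n_layers)]
    spec = ModelSpec(
        input_dim=header["input_dim"],
        n_classes=header["n_classes"],
        hidden=tuple(header["hidden"]),
        dropout=header["dropout"],
        leaky_slope=header["leaky_slope"],
    )
    return TrainedModel(spec, weights, biases, header["class_names"])
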