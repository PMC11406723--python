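"""Feed-forward neural classifier for cell-type prediction from embeddings.

The network maps a cell's embedding through two hidden layers with ReLU
activations to a per-class sigmoid output, one score in (0, 1) per cell
type.  Training minimizes the mean elementwise binary cross-entropy between
the sigmoid scores and one-hot targets (a one-vs-rest view of the multiclass
problem that honours the sigmoid output), by mini-batch gradient descent
with momentum; a softmax + categorical cross-entropy variant is available
via ``ModelConfig.loss``.

Inverted dropout regularizes the hidden layers: at train time each hidden
unit is dropped with probability ``dropout_rate`` and the survivors are
scaled by 1/(1-rate), so inference needs no rescaling.  Early stopping
monitors the loss on a held-out validation split and restores the best
weights.

All randomness (weight initialization, batch shuffling, dropout masks, the
validation split) flows from the single ``ModelConfig.seed``, so training is
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["ModelConfig", "TrainedModel", "forward", "train", "predict", "predict_proba", "dropout_sweep"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters."""

    input_dim: int
    n_classes: int
    hidden_sizes: tuple[int, ...] = (256, 64)
    dropout_rate: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    momentum: float = 0.9
    val_fraction: float = 0.1
    early_stop_patience: int = 10
    loss: str = "bce"  # "bce" (per-class sigmoid) or "softmax"
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1 or self.n_classes < 2:
            raise ValueError("input_dim >= 1 and n_classes >= 2 required")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.loss not in ("bce", "softmax"):
            raise ValueError("loss must be 'bce' or 'softmax'")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _init_weights(config: ModelConfig, rng: np.random.Generator) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Scaled-uniform init, limit sqrt(6 / fan_in) per layer."""
    dims = [config.input_dim, *config.hidden_sizes, config.n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        lim = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


@dataclass
class TrainedModel:
    """Learned weights, the label vocabulary, and the training history."""

    config: ModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: tuple[str, ...]
    history: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self):
        dims = [self.config.input_dim, *self.config.hidden_sizes, self.config.n_classes]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (dims[i], dims[i + 1]) or b.shape != (dims[i + 1],):
                raise ValueError(f"layer {i} shape mismatch: {w.shape}, {b.shape}")

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Versioned archive: weights/biases plus config and label vocabulary."""
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        meta = {
            "format_version": 1,
            "config": {**asdict(self.config), "hidden_sizes": list(self.config.hidden_sizes)},
            "classes": list(self.classes),
            "history": self.history,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = meta["config"]
            cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
            config = ModelConfig(**cfg)
            n_layers = len(config.hidden_sizes) + 1
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
        return cls(config, weights, biases, tuple(meta["classes"]), meta["history"])


def forward(
    model: TrainedModel,
    X: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Forward pass: affine + ReLU per hidden layer, affine + sigmoid output.

    ``train_mode`` activates inverted dropout on hidden activations (requires
    ``rng``).  With ``return_cache`` the intermediate activations and dropout
    masks needed by backprop are returned too.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.config.input_dim:
        raise ValueError(f"X must be (M, {model.config.input_dim}), got {X.shape}")
    rate = model.config.dropout_rate
    if train_mode and rate > 0 and rng is None:
        raise ValueError("train_mode dropout requires an rng")
    a = X
    activations = [a]  # post-dropout inputs to each layer
    pre_acts = []
    masks = []
    n_layers = len(model.weights)
    for i in range(n_layers - 1):
        z = a @ model.weights[i] + model.biases[i]
        pre_acts.append(z)
        a = np.maximum(z, 0.0)
        if train_mode and rate > 0:
            mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
            a = a * mask
            masks.append(mask)
        else:
            masks.append(None)
        activations.append(a)
    z_out = a @ model.weights[-1] + model.biases[-1]
    pre_acts.append(z_out)
    scores = _sigmoid(z_out) if model.config.loss == "bce" else _softmax(z_out)
    if return_cache:
        return scores, {"activations": activations, "pre_acts": pre_acts, "masks": masks}
    return scores


def _loss_value(scores: np.ndarray, Y: np.ndarray, loss: str) -> float:
    eps = 1e-12
    s = np.clip(scores, eps, 1.0 - eps)
    if loss == "bce":
        return float(-np.mean(Y * np.log(s) + (1.0 - Y) * np.log(1.0 - s)))
    return float(-np.mean(np.sum(Y * np.log(s), axis=1)))


def _backward(
    model: TrainedModel, scores: np.ndarray, Y: np.ndarray, cache: dict
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Analytic gradients of the mean loss w.r.t. every weight and bias.

    For both sigmoid+BCE and softmax+CCE the gradient at the output
    pre-activation is (scores - Y) up to the normalizing constant.
    """
    M, C = Y.shape
    norm = M * C if model.config.loss == "bce" else M
    delta = (scores - Y) / norm
    grads_W: list[np.ndarray] = [None] * len(model.weights)
    grads_b: list[np.ndarray] = [None] * len(model.biases)
    for i in range(len(model.weights) - 1, -1, -1):
        a_prev = cache["activations"][i]
        grads_W[i] = a_prev.T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ model.weights[i].T
            mask = cache["masks"][i - 1]
            if mask is not None:
                delta = delta * mask
            delta = delta * (cache["pre_acts"][i - 1] > 0)
    return grads_W, grads_b


def _one_hot(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"unknown label {lab!r}")
        Y[r, index[lab]] = 1.0
    return Y


def train(X: np.ndarray, labels: Sequence[str], config: ModelConfig) -> TrainedModel:
    """Train the network by mini-batch gradient descent with momentum.

    Records per-epoch train/validation loss and accuracy in
    ``model.history``; early stopping watches the validation loss with
    ``early_stop_patience`` and restores the best weights.  With
    ``epochs=0`` the returned model is the seeded initialization and the
    history is empty.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if config.n_classes != len(classes):
        raise ValueError(f"config.n_classes={config.n_classes} but data has {len(classes)} classes")
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_weights(config, rng)
    model = TrainedModel(config, weights, biases, classes, history={})
    Y = _one_hot(labels, classes)
    y_idx = Y.argmax(axis=1)

    # validation split (seeded permutation; no stratification at these sizes)
    M = X.shape[0]
    n_val = int(round(config.val_fraction * M))
    perm = rng.permutation(M)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Y_tr = X[tr_idx], Y[tr_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    vel_W = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    best_val = np.inf
    best_state = None
    patience_left = config.early_stop_patience
    n_tr = X_tr.shape[0]

    for _epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, config.batch_size):
            batch = order[start : start + config.batch_size]
            scores, cache = forward(model, X_tr[batch], train_mode=True, rng=rng, return_cache=True)
            gW, gb = _backward(model, scores, Y_tr[batch], cache)
            for i in range(len(weights)):
                vel_W[i] = config.momentum * vel_W[i] - config.learning_rate * gW[i]
                vel_b[i] = config.momentum * vel_b[i] - config.learning_rate * gb[i]
                weights[i] += vel_W[i]
                biases[i] += vel_b[i]

        tr_scores = forward(model, X_tr)
        tr_loss = _loss_value(tr_scores, Y_tr, config.loss)
        if not np.isfinite(tr_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {_epoch}; reduce the learning rate"
            )
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(float(np.mean(tr_scores.argmax(axis=1) == y_idx[tr_idx])))
        if n_val > 0:
            val_scores = forward(model, X_val)
            val_loss = _loss_value(val_scores, Y_val, config.loss)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(float(np.mean(val_scores.argmax(axis=1) == y_idx[val_idx])))
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = ([w.copy() for w in weights], [b.copy() for b in biases])
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if config.early_stop_patience > 0 and patience_left <= 0:
                    break

    if best_state is not None:
        model.weights, model.biases = best_state
    model.history = history
    return model


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Raw output scores (sigmoid per class, or softmax); not renormalized."""
    return forward(model, X, train_mode=False)


def predict(model: TrainedModel, X: np.ndarray) -> list[str]:
    """Argmax class per cell; ties resolve to the first class in vocabulary order."""
    scores = predict_proba(model, X)
    return [model.classes[i] for i in scores.argmax(axis=1)]


DEFAULT_SWEEP_RATES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


def dropout_sweep(
    X: np.ndarray,
    labels: Sequence[str],
    rates: Sequence[float] = DEFAULT_SWEEP_RATES,
    config: ModelConfig | None = None,
    test_fraction: float = 0.3,
) -> list[dict[str, float]]:
    """Train one model per dropout rate on one fixed seeded split; report held-out ARI/NMI/ACC."""
    from .metrics import accuracy, ari, nmi

    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if config is None:
        config = ModelConfig(input_dim=X.shape[1], n_classes=len(set(labels)))
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(labels))
    n_test = int(round(test_fraction * len(labels)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    X_train, X_test = X[train_idx], X[test_idx]
    labels_train = [labels[i] for i in train_idx]
    labels_test = [labels[i] for i in test_idx]

    rows = []
    for rate in rates:
        cfg = replace(config, dropout_rate=rate)
        model = train(X_train, labels_train, cfg)
        pred = predict(model, X_test)
        rows.append(
            {
                "rate": float(rate),
                "acc": accuracy(labels_test, pred),
                "ari": ari(labels_test, pred),
                "nmi": nmi(labels_test, pred),
            }
        )
    return rows
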