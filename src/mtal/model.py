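"""Hard-parameter-sharing multitask classifier.

A deliberately small reference model: a shared multilayer perceptron trunk
(ReLU) feeding one softmax head per task, trained with Adam on the weighted
multitask cross-entropy

    L = sum_i alpha_i * CE_i + l2 * ||W||^2 ,

where CE_i is the mean cross-entropy of task i over the labeled batch and
alpha_i the task weight. The active-learning query strategies only require the
probabilistic fit/predict contract, so the trunk is interchangeable; this
implementation is pure numpy, fully deterministic under a seed, and fast enough
to be retrained from scratch at every query iteration.

Tasks with classes unobserved in the labeled pool (routine when training starts
from a 3-sample seed) train normally: every head always has its full C_i-way
softmax, and unobserved classes simply receive no label gradient.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import MultitaskDataset, TaskSpec
from .exceptions import EmptyPoolError

__all__ = ["ModelConfig", "TrainedModel", "fit", "predict_proba", "multitask_loss", "evaluate_accuracy"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    ``shared_layer_widths`` may be empty, in which case each head is a
    multinomial logit on the raw features. ``l2_factor`` multiplies the squared
    Frobenius norm of all weight matrices (biases unpenalised).
    """

    shared_layer_widths: tuple[int, ...] = (32,)
    dropout_rate: float = 0.0
    l2_factor: float = 0.01
    epochs: int = 150
    learning_rate: float = 0.01
    batch_size: int = 32
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_factor < 0:
            raise ValueError("l2_factor must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=int(seed))


@dataclass
class TrainedModel:
    """Fitted parameter state plus the task list and a training-set fingerprint."""

    shared: list[tuple[np.ndarray, np.ndarray]]
    heads: list[tuple[np.ndarray, np.ndarray]]
    tasks: list[TaskSpec]
    config: ModelConfig
    n_features: int
    fingerprint: str
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_trunk(shared, X):
    h = X
    for W, b in shared:
        h = np.maximum(h @ W + b, 0.0)
    return h


def multitask_loss(
    probabilities: list[np.ndarray],
    labels: np.ndarray,
    weights: np.ndarray | list[float],
) -> float:
    """Weighted multitask cross-entropy: sum_i alpha_i * mean CE of task i.

    ``probabilities[i]`` is an (n, C_i) row-normalised matrix and ``labels`` the
    (n, T) integer label matrix. Zero iff every true class has probability 1.
    """
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=float)
    if labels.ndim != 2 or labels.shape[1] != len(probabilities) or len(weights) != len(probabilities):
        raise ValueError("need one probability matrix and one weight per label column")
    total = 0.0
    for i, probs in enumerate(probabilities):
        probs = np.asarray(probs, dtype=float)
        if probs.shape[0] != labels.shape[0]:
            raise ValueError(f"task {i}: probability rows do not match label rows")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"task {i}: probability rows are not normalised")
        p_true = probs[np.arange(labels.shape[0]), labels[:, i]]
        total += weights[i] * float(-np.log(np.clip(p_true, 1e-12, 1.0)).mean())
    return total


def fit(
    config: ModelConfig,
    features: np.ndarray,
    labels: np.ndarray,
    tasks: list[TaskSpec],
) -> TrainedModel:
    """Train the shared-trunk multitask network on a labeled pool.

    Deterministic under ``config.seed`` (initialisation, dropout masks and
    minibatch order all derive from it). Raises EmptyPoolError on an empty
    labeled set.
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(labels, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise EmptyPoolError("cannot fit on an empty labeled pool")
    if Y.shape != (X.shape[0], len(tasks)):
        raise ValueError("labels must be (n, T) aligned with features and tasks")
    n, D = X.shape
    rng = np.random.default_rng(config.seed)

    widths = [D, *config.shared_layer_widths]
    shared = [
        (rng.standard_normal((widths[i], widths[i + 1])) * np.sqrt(2.0 / widths[i]),
         np.zeros(widths[i + 1]))
        for i in range(len(widths) - 1)
    ]
    top = widths[-1]
    heads = [
        (rng.standard_normal((top, t.n_classes)) * np.sqrt(2.0 / top), np.zeros(t.n_classes))
        for t in tasks
    ]

    alphas = np.array([t.weight for t in tasks], dtype=float)
    sample_w = _per_task_sample_weights(Y, tasks) if config.class_weighting else None

    params = [p for layer in shared + heads for p in layer]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    batch = min(config.batch_size, n)
    history = []

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Xb, Yb = X[idx], Y[idx]
            nb = len(idx)

            # forward through shared trunk with inverted dropout
            acts = [Xb]
            masks = []
            h = Xb
            for W, b in shared:
                h = np.maximum(h @ W + b, 0.0)
                if config.dropout_rate > 0.0:
                    mask = (rng.random(h.shape) >= config.dropout_rate) / (1.0 - config.dropout_rate)
                    h = h * mask
                    masks.append(mask)
                acts.append(h)

            grads = [np.zeros_like(p) for p in params]
            d_h = np.zeros_like(h)
            data_loss = 0.0
            for i, (Wh, bh) in enumerate(heads):
                probs = _softmax(h @ Wh + bh)
                onehot = np.zeros_like(probs)
                onehot[np.arange(nb), Yb[:, i]] = 1.0
                w = sample_w[i][idx][:, None] if sample_w is not None else 1.0 / nb
                if sample_w is not None:
                    w = w / max(float(np.sum(sample_w[i][idx])), 1e-12)
                d_logits = alphas[i] * (probs - onehot) * w
                p_true = np.clip(probs[np.arange(nb), Yb[:, i]], 1e-12, 1.0)
                if sample_w is not None:
                    ws = sample_w[i][idx]
                    data_loss += alphas[i] * float(-(ws * np.log(p_true)).sum() / max(ws.sum(), 1e-12))
                else:
                    data_loss += alphas[i] * float(-np.log(p_true).mean())
                hi = len(shared) * 2 + i * 2
                grads[hi] += h.T @ d_logits
                grads[hi + 1] += d_logits.sum(axis=0)
                d_h += d_logits @ Wh.T

            # back through trunk
            for li in range(len(shared) - 1, -1, -1):
                if config.dropout_rate > 0.0:
                    d_h = d_h * masks[li]
                d_h = d_h * (acts[li + 1] > 0)
                W, _b = shared[li]
                grads[li * 2] += acts[li].T @ d_h
                grads[li * 2 + 1] += d_h.sum(axis=0)
                d_h = d_h @ W.T

            # l2 on weight matrices only
            reg = 0.0
            if config.l2_factor > 0.0:
                for pi in range(0, len(params), 2):
                    grads[pi] += 2.0 * config.l2_factor * params[pi]
                    reg += config.l2_factor * float(np.sum(params[pi] ** 2))

            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for pi, (p, g) in enumerate(zip(params, grads)):
                adam_m[pi] = beta1 * adam_m[pi] + (1 - beta1) * g
                adam_v[pi] = beta2 * adam_v[pi] + (1 - beta2) * g * g
                p -= lr_t * adam_m[pi] / (np.sqrt(adam_v[pi]) + eps)

            epoch_loss += data_loss + reg
            n_batches += 1
        history.append(epoch_loss / n_batches)

    digest = hashlib.sha1(X.tobytes() + Y.tobytes()).hexdigest()[:16]
    return TrainedModel(
        shared=shared,
        heads=heads,
        tasks=list(tasks),
        config=config,
        n_features=D,
        fingerprint=digest,
        loss_history=np.asarray(history),
    )


def _per_task_sample_weights(Y: np.ndarray, tasks: list[TaskSpec]) -> list[np.ndarray]:
    """Inverse-frequency weights per task; unobserved classes carry no samples."""
    n = Y.shape[0]
    out = []
    for i, t in enumerate(tasks):
        counts = np.bincount(Y[:, i], minlength=t.n_classes).astype(float)
        cls_w = np.where(counts > 0, n / (t.n_classes * np.maximum(counts, 1)), 0.0)
        out.append(cls_w[Y[:, i]])
    return out


def predict_proba(model: TrainedModel, features: np.ndarray) -> list[np.ndarray]:
    """Per-task class probability matrices for ``features`` (rows sum to 1)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[-1] if X.ndim == 2 else '?'} does not match "
            f"training width {model.n_features}"
        )
    h = _forward_trunk(model.shared, X)
    return [_softmax(h @ W + b) for W, b in model.heads]


def evaluate_accuracy(
    model: TrainedModel,
    dataset: MultitaskDataset,
    split: str = "test",
) -> tuple[np.ndarray, float]:
    """Per-task accuracy on a dataset split plus the arithmetic mean over tasks."""
    X, Y = dataset.split(split)
    probs = predict_proba(model, X)
    per_task = np.array([
        float((p.argmax(axis=1) == Y[:, i]).mean()) for i, p in enumerate(probs)
    ])
    return per_task, float(per_task.mean())
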