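"""Optimisation: categorical cross-entropy, Adam, dataset sharding, gradient
averaging across simulated data-parallel workers, and the fit loop with
lowest-loss checkpointing.

The data-parallel contract mirrors synchronous all-reduce training: the batch
is partitioned into per-worker shards, each worker computes the gradient of
its local mean loss, gradients are averaged element-wise, and one identical
parameter update is applied. With equal shard sizes this reproduces the
single-process full-batch gradient exactly (up to floating-point round-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .autograd import Tensor
from .graph_construction import GraphBatch, ImageGraph
from .model import HybridModel

__all__ = [
    "TrainConfig",
    "Shard",
    "Sample",
    "Adam",
    "cross_entropy",
    "softmax_cross_entropy",
    "shard_dataset",
    "sync_gradients",
    "train_epoch",
    "evaluate_loss",
    "predict",
    "fit",
    "FitResult",
]

_EPS = 1e-12  # probability clamp inside the loss; keeps -log finite


class Sample(NamedTuple):
    """One training example: an image graph, the raw image, and its label."""

    graph: ImageGraph
    image: np.ndarray
    label: int


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    num_workers: int = 1
    seed: int = 0
    checkpoint_policy: str = "lowest_train_loss"  # or "lowest_val_loss"
    mode: str = "hybrid"  # "hybrid", "graph_only" or "image_only"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if min(self.epochs, self.batch_size, self.num_workers) < 1:
            raise ValueError("epochs, batch_size and num_workers must be >= 1")
        if self.checkpoint_policy not in ("lowest_train_loss", "lowest_val_loss"):
            raise ValueError(f"unknown checkpoint_policy {self.checkpoint_policy!r}")


@dataclass
class Shard:
    """A worker's slice of the dataset (sample indices)."""

    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Categorical cross-entropy -sum_c y_c log(p_c) on probability vectors.

    Accepts a single one-hot/probability pair or batches (mean over rows).
    Predicted probabilities are clamped at 1e-12 so the loss is always finite.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    if np.any(np.abs(y_pred.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each predicted probability vector must sum to 1")
    losses = -(y_true * np.log(np.clip(y_pred, _EPS, 1.0))).sum(axis=1)
    return float(losses.mean())


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits), differentiable."""
    labels = np.asarray(labels, dtype=np.int64)
    n, c = logits.data.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, stabilises exp
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    true_logit = (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (log_norm - true_logit).mean()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# optimiser
# --------------------------------------------------------------------------

class SGD:
    """Plain gradient descent: theta <- theta - lr * grad."""

    def __init__(self, params: dict[str, Tensor], learning_rate: float = 1e-2):
        self.params = dict(sorted(params.items()))
        self.lr = learning_rate

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        for p in self.params.values():
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad


class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(
        self,
        params: dict[str, Tensor],
        learning_rate: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = dict(sorted(params.items()))
        self.lr = learning_rate
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# --------------------------------------------------------------------------
# data-parallel contract
# --------------------------------------------------------------------------

def shard_dataset(dataset_size: int, num_workers: int, seed: int = 0) -> list[Shard]:
    """Partition sample indices into disjoint, covering, balanced shards."""
    if num_workers < 1:
        raise ValueError("num_workers must be >= 1")
    if num_workers > dataset_size:
        raise ValueError("cannot use more workers than dataset samples")
    perm = np.random.default_rng(seed).permutation(dataset_size)
    return [Shard(indices=part) for part in np.array_split(perm, num_workers)]


def sync_gradients(local_gradients: Sequence[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Element-wise mean of per-worker gradient sets (the all-reduce step)."""
    if not local_gradients:
        raise ValueError("no gradients to synchronise")
    ref = local_gradients[0]
    for grads in local_gradients[1:]:
        if set(grads) != set(ref):
            raise ValueError("gradient sets name different parameters")
        for name in ref:
            if grads[name].shape != ref[name].shape:
                raise ValueError(f"gradient shape mismatch for {name!r}")
    return {
        name: np.mean([grads[name] for grads in local_gradients], axis=0) for name in ref
    }


# --------------------------------------------------------------------------
# epoch loop
# --------------------------------------------------------------------------

def _collate(samples: Sequence[Sample], mode: str):
    labels = np.array([s.label for s in samples], dtype=np.int64)
    batch = GraphBatch.from_graphs([s.graph for s in samples]) if mode != "image_only" else None
    images = np.stack([s.image for s in samples]) if mode != "graph_only" else None
    return batch, images, labels


def _batch_loss(model: HybridModel, samples: Sequence[Sample], mode: str, training: bool) -> Tensor:
    batch, images, labels = _collate(samples, mode)
    logits = model.forward(batch, images, mode=mode, training=training)
    return softmax_cross_entropy(logits, labels)


def _local_gradients(
    model: HybridModel, samples: Sequence[Sample], mode: str
) -> tuple[dict[str, np.ndarray], float]:
    params = model.parameters(trainable_only=True)
    model.zero_grad()
    loss = _batch_loss(model, samples, mode, training=True)
    loss.backward()
    grads = {
        name: (p.grad.copy() if p.grad is not None else np.zeros_like(p.data))
        for name, p in params.items()
    }
    return grads, float(loss.data)


def train_epoch(
    model: HybridModel,
    data: Sequence[Sample],
    optimizer: Adam,
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """One pass over ``data``; returns the mean per-batch training loss.

    With ``num_workers > 1`` each batch is split into contiguous equal-size
    shards, per-shard gradients of the local mean loss are averaged, and a
    single synchronous update is applied — the in-process equivalent of
    synchronous data-parallel training.
    """
    if len(data) == 0:
        raise ValueError("training data must be non-empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    order = rng.permutation(len(data))
    batch_losses = []
    for start in range(0, len(order), config.batch_size):
        idx = order[start : start + config.batch_size]
        samples = [data[i] for i in idx]
        workers = min(config.num_workers, len(samples))
        if workers == 1:
            grads, loss_val = _local_gradients(model, samples, config.mode)
        else:
            shards = np.array_split(np.arange(len(samples)), workers)
            locals_, losses = [], []
            for shard in shards:
                g, l = _local_gradients(model, [samples[i] for i in shard], config.mode)
                locals_.append(g)
                losses.append(l)
            grads = sync_gradients(locals_)
            loss_val = float(np.mean(losses))
        params = model.parameters(trainable_only=True)
        for name, p in params.items():
            p.grad = grads[name]
        optimizer.step()
        optimizer.zero_grad()
        batch_losses.append(loss_val)
    return float(np.mean(batch_losses))


def evaluate_loss(model: HybridModel, data: Sequence[Sample], mode: str, batch_size: int = 64) -> float:
    """Mean cross-entropy over ``data`` in evaluation mode (no dropout)."""
    losses, weights = [], []
    for start in range(0, len(data), batch_size):
        chunk = data[start : start + batch_size]
        losses.append(float(_batch_loss(model, chunk, mode, training=False).data))
        weights.append(len(chunk))
    return float(np.average(losses, weights=weights))


def predict(model: HybridModel, data: Sequence[Sample], mode: str, batch_size: int = 64) -> np.ndarray:
    """Class predictions in evaluation mode."""
    preds = []
    for start in range(0, len(data), batch_size):
        chunk = data[start : start + batch_size]
        batch, images, _ = _collate(chunk, mode)
        logits = model.forward(batch, images, mode=mode, training=False)
        preds.append(np.argmax(logits.data, axis=1))
    return np.concatenate(preds)


@dataclass
class FitResult:
    best_state: dict[str, np.ndarray]
    best_epoch: int  # 1-based
    history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)


def fit(
    model: HybridModel,
    train_data: Sequence[Sample],
    config: TrainConfig,
    val_data: Sequence[Sample] | None = None,
) -> FitResult:
    """Train for ``config.epochs`` epochs, checkpointing the lowest-loss epoch.

    The tracked loss is the running training loss by default, or the
    validation loss when ``checkpoint_policy == "lowest_val_loss"`` (which
    then requires ``val_data``). The returned ``best_state`` restores the
    checkpointed parameters via ``model.load_state_dict``.
    """
    if config.checkpoint_policy == "lowest_val_loss" and val_data is None:
        raise ValueError("lowest_val_loss checkpointing requires validation data")
    model.reseed_dropout(config.seed + 1)
    optimizer = Adam(model.parameters(trainable_only=True), learning_rate=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed)
    history: list[float] = []
    val_history: list[float] = []
    best_metric = np.inf
    best_epoch = 0
    best_state = model.state_dict()
    for epoch in range(1, config.epochs + 1):
        train_loss = train_epoch(model, train_data, optimizer, config, rng=shuffle_rng)
        history.append(train_loss)
        tracked = train_loss
        if val_data is not None:
            val_loss = evaluate_loss(model, val_data, config.mode)
            val_history.append(val_loss)
            if config.checkpoint_policy == "lowest_val_loss":
                tracked = val_loss
        if tracked < best_metric:
            best_metric = tracked
            best_epoch = epoch
            best_state = model.state_dict()
    # pin batch-norm statistics of the checkpointed parameters to the full
    # training set so evaluation-mode behaviour matches the fitted model
    model.load_state_dict(best_state)
    batch, images, _ = _collate(train_data, config.mode)
    model.calibrate_norms(batch, images, mode=config.mode)
    best_state = model.state_dict()
    return FitResult(best_state=best_state, best_epoch=best_epoch, history=history, val_history=val_history)
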