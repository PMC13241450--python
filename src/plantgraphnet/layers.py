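"""Neural building blocks: linear maps, message-passing layers, normalisers,
dropout and a compact convolutional image backbone.

All learnable weight matrices use Xavier-uniform initialisation and all biases
start at exactly zero. Message passing follows the two-step scheme: aggregate
neighbour states, combine with the node's own state, then normalise, dropout
and apply the nonlinearity (in that order).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, avg_pool_2x2, gather_rows, segment_sum

__all__ = [
    "xavier_uniform",
    "Module",
    "Linear",
    "GraphConvLayer",
    "GraphAttentionLayer",
    "BatchNorm",
    "LayerNorm",
    "IdentityNorm",
    "dropout",
    "global_add_pool",
    "ConvBackbone",
]


def xavier_uniform(fan_in: int, fan_out: int, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: children register parameters in ``self._params``."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray, requires_grad: bool = True) -> Tensor:
        t = Tensor(value, requires_grad=requires_grad)
        self._params[name] = t
        return t

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def parameters(self, trainable_only: bool = False) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, p in self._params.items():
            if not trainable_only or p.requires_grad:
                out[name] = p
        for cname, child in self._children.items():
            for name, p in child.parameters(trainable_only).items():
                out[f"{cname}.{name}"] = p
        return out

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()


class Linear(Module):
    """Affine map ``x @ W + b`` with W Xavier-uniform and b zero at init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.W = self.add_param(
            "W", xavier_uniform(in_features, out_features, (in_features, out_features), rng)
        )
        self.b = self.add_param("b", np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: zero units with probability ``p`` during training."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(mask)


def global_add_pool(h: Tensor, batch_vector: np.ndarray, num_graphs: int) -> Tensor:
    """Sum node embeddings into one row per graph."""
    return segment_sum(h, batch_vector, num_graphs)


class GraphConvLayer(Module):
    """Degree-normalised convolution: mean of edge-weighted neighbour states,
    combined with the node's own state through two learned linear maps.

    Isolated nodes receive a zero aggregation term, so their update depends
    only on their own previous state.
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.W_self = self.add_param(
            "W_self", xavier_uniform(in_features, out_features, (in_features, out_features), rng)
        )
        self.W_neigh = self.add_param(
            "W_neigh", xavier_uniform(in_features, out_features, (in_features, out_features), rng)
        )
        self.b = self.add_param("b", np.zeros(out_features))

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_attr: np.ndarray) -> Tensor:
        n = h.data.shape[0]
        self_term = h @ self.W_self
        if edge_index.size == 0:
            return self_term + self.b
        src, tgt = edge_index[:, 0], edge_index[:, 1]
        deg = np.bincount(tgt, minlength=n).astype(np.float64)
        inv_deg = 1.0 / np.maximum(deg, 1.0)
        msg = gather_rows(h, src) * Tensor(edge_attr[:, None])
        agg = segment_sum(msg, tgt, n) * Tensor(inv_deg[:, None])
        return self_term + agg @ self.W_neigh + self.b


class GraphAttentionLayer(Module):
    """Single-head attention-weighted aggregation over incoming edges.

    Attention logits are leaky-ReLU of a learned function of the projected
    source and target states, soft-maxed per target node; edge attributes
    multiply the attention weights so weighted graphs reuse the same path.
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.W = self.add_param(
            "W", xavier_uniform(in_features, out_features, (in_features, out_features), rng)
        )
        self.a_src = self.add_param(
            "a_src", xavier_uniform(out_features, 1, (out_features, 1), rng)
        )
        self.a_tgt = self.add_param(
            "a_tgt", xavier_uniform(out_features, 1, (out_features, 1), rng)
        )
        self.b = self.add_param("b", np.zeros(out_features))

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_attr: np.ndarray) -> Tensor:
        n = h.data.shape[0]
        hp = h @ self.W
        if edge_index.size == 0:
            return hp + self.b
        src, tgt = edge_index[:, 0], edge_index[:, 1]
        score = (
            gather_rows(hp @ self.a_src, src) + gather_rows(hp @ self.a_tgt, tgt)
        ).leaky_relu(0.2)
        # numerically stable per-target softmax; the max shift is a constant
        shift = np.full(n, -np.inf)
        np.maximum.at(shift, tgt, score.data[:, 0])
        shift[~np.isfinite(shift)] = 0.0
        ez = (score - Tensor(shift[tgt][:, None])).exp() * Tensor(edge_attr[:, None])
        denom = segment_sum(ez, tgt, n)
        alpha = ez / (gather_rows(denom, tgt) + 1e-16)
        agg = segment_sum(gather_rows(hp, src) * alpha, tgt, n)
        return hp + agg + self.b


class BatchNorm(Module):
    """Batch normalisation over the node/sample axis with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.calibrating = False
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if self.calibrating:
            # one-shot recalibration: running statistics become the statistics
            # of the batch being passed through (normalisation uses them too)
            self.running_mean = x.data.mean(axis=0)
            self.running_var = x.data.var(axis=0)
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            )
            inv = (var + self.eps).pow(-0.5)
            return (x - mu) * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - Tensor(self.running_mean)) * Tensor(inv) * self.gamma + self.beta

    # running statistics must survive checkpointing
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = np.array(state["running_mean"], copy=True)
        self.running_var = np.array(state["running_var"], copy=True)


class LayerNorm(Module):
    """Per-row normalisation over the feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = self.add_param("gamma", np.ones(dim))
        self.beta = self.add_param("beta", np.zeros(dim))

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=1, keepdims=True)
        return (x - mu) * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class IdentityNorm(Module):
    """No-op normaliser (used in hand-checkable configurations)."""

    def __init__(self, dim: int):
        super().__init__()

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return x


class ConvBackbone(Module):
    """Compact convolutional image encoder.

    Three 3x3 convolution blocks (ReLU + 2x2 average pooling after the first
    two) followed by global average pooling, producing one feature vector of
    width ``channels[-1]`` per image. Deterministically initialised from a
    seed; when frozen its parameters carry no gradient and it acts as a fixed
    random-feature extractor in front of the learned linear projection.
    """

    def __init__(
        self,
        channels: tuple[int, int, int] = (16, 32, 64),
        in_channels: int = 3,
        frozen: bool = True,
        seed: int = 0,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.frozen = frozen
        chain = (in_channels,) + self.channels
        for i in range(3):
            cin, cout = chain[i], chain[i + 1]
            fan_in, fan_out = cin * 9, cout * 9
            self.add_param(
                f"conv{i}.W",
                xavier_uniform(fan_in, fan_out, (cout, cin, 3, 3), rng),
                requires_grad=not frozen,
            )
            self.add_param(f"conv{i}.b", np.zeros(cout), requires_grad=not frozen)

    @property
    def out_features(self) -> int:
        return self.channels[-1]

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(3):
            x = conv2d(x, self._params[f"conv{i}.W"], self._params[f"conv{i}.b"], padding=1)
            x = x.relu()
            if i < 2:
                x = avg_pool_2x2(x)
        return x.mean(axis=(2, 3))
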