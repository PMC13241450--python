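"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the package's networks need: broadcasted
arithmetic, matmul, elementwise nonlinearities, axis reductions, reshape /
concatenate, row gather / segment scatter-add (the message-passing primitives),
2-D convolution via im2col and 2x2 average pooling. Everything is float64;
gradients accumulate into ``Tensor.grad`` after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "conv2d",
    "avg_pool_2x2",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self._needs(other))
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))

            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self._needs(other))
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))

            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(np.power(self.data, exponent), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(
                g * exponent * np.power(self.data, exponent - 1.0)
            )
        return out

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self._needs(other))
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)

            out._backward = _bw
        return out

    # ----------------------------------------------------------- nonlinearity
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def leaky_relu(self, alpha: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(
                g * np.where(self.data > 0, 1.0, alpha)
            )
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes: tuple[int, ...]):
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        if out.requires_grad:
            inv = tuple(np.argsort(axes))
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each input."""
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]``; backward scatter-adds into the source rows."""
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(x.data[index], x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw(g):
            acc = np.zeros_like(x.data)
            np.add.at(acc, index, g)
            x._accumulate(acc)

        out._backward = _bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``segment_ids``."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    if segment_ids.size and (segment_ids.min() < 0 or segment_ids.max() >= num_segments):
        raise ValueError("segment ids out of range")
    val = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(val, segment_ids, x.data)
    out = Tensor(val, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g[segment_ids])
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 1) -> Tensor:
    """Stride-1 2-D convolution, NCHW layout, via im2col.

    ``weight`` has shape (out_ch, in_ch, kh, kw); ``bias`` shape (out_ch,).
    """
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # (B, C, Ho, Wo, kh, kw) -> (B*Ho*Wo, C*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, C * kh * kw)
    val = (cols @ wmat.T + bias.data).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    out = Tensor(val, x.requires_grad or weight.requires_grad or bias.requires_grad)
    if out.requires_grad:
        out._parents = (x, weight, bias)

        def _bw(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
            if weight.requires_grad:
                weight._accumulate((g2.T @ cols).reshape(O, C, kh, kw))
            if bias.requires_grad:
                bias._accumulate(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ wmat).reshape(B, Ho, Wo, C, kh, kw)
                gpad = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gpad[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, :, :, i, j].transpose(
                            0, 3, 1, 2
                        )
                if padding:
                    gpad = gpad[:, :, padding:-padding, padding:-padding]
                x._accumulate(gpad)

        out._backward = _bw
    return out


def avg_pool_2x2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (even spatial dims required)."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool_2x2 requires even spatial dimensions")
    val = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = Tensor(val, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw(g):
            up = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(up)

        out._backward = _bw
    return out
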