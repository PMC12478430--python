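"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's encoders and losses need:
broadcasting arithmetic, (batched) matmul, elementwise nonlinearities,
reductions, embedding lookup, slicing and concatenation.  All data is
float64, which keeps finite-difference gradient checks tight and makes
training runs bit-reproducible across platforms.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---------------------------------------------------------------- basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, p: float) -> "Tensor":
        assert np.isscalar(p), "only scalar exponents are supported"

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def bw(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # ---------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False) -> "Tensor":
        # detached max gives the exact softmax gradient while staying stable
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(np.delete(out.data.shape, axis)))
        return out

    def softmax(self, axis: int) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ----------------------------------------------------------- structural
    def reshape(self, shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bw(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)

        return self._make(self.data[idx], (self,), bw)

    def take(self, indices: np.ndarray) -> "Tensor":
        """Row gather (embedding lookup): self is (V, h), indices any int shape."""
        indices = np.asarray(indices)

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, indices, g)
            self._accum(buf)

        return self._make(self.data[indices], (self,), bw)

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )
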