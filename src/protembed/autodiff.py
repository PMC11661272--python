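"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The networks in this package are small enough (a few million parameters,
graphs with at most a few thousand edges) that a tape-based engine over
dense ``float64`` arrays is fast and, more importantly, auditable: every
operation's gradient is verified against central finite differences in the
test suite.

Only the operations the graph networks need are provided: broadcast
arithmetic, matrix multiplication, gather/segment primitives for message
passing, layer normalization, dropout and the activations used by the
architecture (ReLU and shifted softplus).
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "gather",
    "segment_sum",
    "segment_mean",
    "segment_softmax",
    "layer_norm",
    "dropout",
    "shifted_softplus",
    "relu",
]

LN2 = math.log(2.0)


def _scatter_add(target: np.ndarray, index: np.ndarray, values: np.ndarray) -> None:
    """target[index] += values with duplicate indices, via sort + reduceat.

    Equivalent to ``np.add.at`` but vectorized row-wise, which is much
    faster for the wide per-edge arrays used in message passing.
    """
    if len(index) == 0:
        return
    order = np.argsort(index, kind="stable")
    sorted_index = index[order]
    sorted_values = values[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(sorted_index)) + 1])
    target[sorted_index[starts]] += np.add.reduceat(sorted_values, starts, axis=0)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- infrastructure -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        # grad arrays are never mutated in place anywhere in the engine, so
        # the first accumulation may share storage; later ones reallocate.
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                node.grad = None if node._backward is not None else node.grad

    # -- arithmetic ------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor(-self.data, parents=(a,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(self.data * other.data, parents=(a, b), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return Tensor(self.data / other.data, parents=(a, b), backward=bwd)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other
        out = a.data @ b.data

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor(out, parents=(a, b), backward=bwd)

    def __pow__(self, exponent: float):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(a,), backward=bwd)

    # -- reductions / reshaping -----------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(a,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        orig = self.data.shape

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(a,), backward=bwd)

    def __getitem__(self, key):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accumulate(full)

        return Tensor(self.data[key], parents=(a,), backward=bwd)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- free functions -------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(np.where(mask, x.data, 0.0), parents=(x,), backward=bwd)


def shifted_softplus(x: Tensor) -> Tensor:
    """ssp(x) = ln(1 + exp(x)) - ln 2; zero at the origin, stable for large |x|."""
    e = np.exp(-np.abs(x.data))  # in (0, 1]; one transcendental pass
    out = np.maximum(x.data, 0.0) + np.log1p(e) - LN2
    sig = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * sig)

    return Tensor(out, parents=(x,), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Row lookup along axis 0 (embedding lookup / edge endpoint gather)."""
    index = np.asarray(index, dtype=np.intp)

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            _scatter_add(full, index, g)
            x._accumulate(full)

    return Tensor(x.data[index], parents=(x,), backward=bwd)


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    segments = np.asarray(segments, dtype=np.intp)
    out = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    _scatter_add(out, segments, x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[segments])

    return Tensor(out, parents=(x,), backward=bwd)


def segment_mean(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    segments = np.asarray(segments, dtype=np.intp)
    counts = np.bincount(segments, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0).reshape((num_segments,) + (1,) * (x.ndim - 1))
    return segment_sum(x, segments, num_segments) * Tensor(1.0 / counts)

def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` within each segment (attention over in-neighbors).

    ``scores`` has shape (E, ...) with one row per edge; the softmax runs over
    all rows sharing a segment id, independently per trailing component.
    """
    segments = np.asarray(segments, dtype=np.intp)
    trailing = scores.data.shape[1:]
    maxes = np.full((num_segments,) + trailing, -np.inf)
    np.maximum.at(maxes, segments, scores.data)
    shifted = scores.data - maxes[segments]
    ex = np.exp(shifted)
    denom = np.zeros((num_segments,) + trailing, dtype=np.float64)
    np.add.at(denom, segments, ex)
    probs = ex / denom[segments]

    def bwd(g):
        if scores.requires_grad:
            inner = np.zeros((num_segments,) + trailing, dtype=np.float64)
            np.add.at(inner, segments, probs * g)
            scores._accumulate(probs * (g - inner[segments]))

    return Tensor(probs, parents=(scores,), backward=bwd)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learnable affine."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gain.data * xhat + bias.data

    def bwd(g):
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.data.shape))
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.data.shape))
        if x.requires_grad:
            gy = g * gain.data
            m1 = gy.mean(axis=-1, keepdims=True)
            m2 = (gy * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gy - m1 - xhat * m2))

    return Tensor(out, parents=(x, gain, bias), backward=bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; the identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)
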