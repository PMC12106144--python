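"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: every node is a :class:`Tensor` holding a
float64 array; operations build a DAG and ``backward()`` runs a topological
sweep accumulating gradients into ``.grad``.  Only the primitives the
recurrent behaviour models need are implemented (elementwise arithmetic
with broadcasting, 2-D matmul, tanh/sigmoid/relu, row softmax, column
slicing/concatenation, sum/mean).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- graph construction ---------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))
        def bwd(g):
            self._accum(g)
            other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))
        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))
        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))
        def bwd(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accum(full)
        out._backward = bwd
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def square(self):
        out = Tensor(self.data ** 2, (self,))
        out._backward = lambda g: self._accum(g * 2.0 * self.data)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g / n, self.data.shape))
        return out

    # ---- backward sweep --------------------------------------------------

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort (graphs can be deep for long windows)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bwd
    return out


def softmax_rows(x: Tensor) -> Tensor:
    """Row-wise softmax of a 2-D tensor (numerically shifted)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)
    out = Tensor(y, (x,))
    def bwd(g):
        dot = (g * y).sum(axis=1, keepdims=True)
        x._accum(y * (g - dot))
    out._backward = bwd
    return out
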