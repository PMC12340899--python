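"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the representation networks, outcome heads
and conditional flows need: broadcasted arithmetic, matmul, elementwise
transcendentals, reductions, reshape/concatenate and boolean masking with
constant masks.  Gradients are accumulated by topological-order backward
passes, numpy-vectorised throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "exp", "log", "tanh", "sigmoid", "softplus", "sqrt"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the graph reachable from self
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data ** p, (a,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(a.data[idx], (a,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if a.requires_grad:
                if axis is None:
                    a._accum(np.broadcast_to(g, a.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


# -- elementwise functions ---------------------------------------------------

def _unary(x: Tensor, fval: np.ndarray, dfun) -> Tensor:
    def bw(g):
        if x.requires_grad:
            x._accum(g * dfun())

    return x._make(fval, (x,), bw)


def exp(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    val = np.exp(x.data)
    return _unary(x, val, lambda: val)


def log(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    return _unary(x, np.log(x.data), lambda: 1.0 / x.data)


def sqrt(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    val = np.sqrt(x.data)
    return _unary(x, val, lambda: 0.5 / val)


def tanh(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    val = np.tanh(x.data)
    return _unary(x, val, lambda: 1.0 - val ** 2)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    val = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                   np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    return _unary(x, val, lambda: val * (1.0 - val))


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
    x = Tensor._lift(x)
    val = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    sig = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                   np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    return _unary(x, val, lambda: sig)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out
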