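"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the network architectures need: affine maps,
element-wise nonlinearities, concatenation/slicing, stable softmax, and
reductions.  Gradients flow through a tape built during the forward pass;
``backward`` traverses it in reverse topological order.  Broadcasting in
``add``/``mul``/``sub`` is handled by summing gradients over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tanh", "sigmoid", "softmax", "concat", "slice_cols",
           "slice_last", "mean", "matmul", "gmatmul", "select", "exp",
           "logsumexp"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _binary(a, b, out, da, db) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = a.requires_grad or b.requires_grad
    res = Tensor(out(a.data, b.data), requires_grad=req, parents=(a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(da(g, a.data, b.data), a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(db(g, a.data, b.data), b.data.shape))

    res._backward = backward
    return res


def add(a, b):
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b):
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def mul(a, b):
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    res = Tensor(a.data @ b.data, requires_grad=a.requires_grad or b.requires_grad, parents=(a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    res._backward = backward
    return res


def gmatmul(a, b):
    """Grouped/batched matmul via numpy broadcasting on stacked matrices.

    Typical use: a (N, B, d) @ b (N, d, k) -> (N, B, k), keeping the N groups
    separate.  A 2-D ``b`` broadcasts across groups; its gradient is summed
    over the group axis.
    """
    a, b = _as_tensor(a), _as_tensor(b)
    res = Tensor(np.matmul(a.data, b.data),
                 requires_grad=a.requires_grad or b.requires_grad, parents=(a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._parents:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    res._backward = backward
    return res


def select(a, index: int):
    """Select one group along axis 0: (N, ...) -> (...)."""
    a = _as_tensor(a)
    res = Tensor(a.data[index], requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            full = np.zeros_like(a.data)
            full[index] = g
            a._accumulate(full)

    res._backward = backward
    return res


def _unary(a, out, da) -> Tensor:
    a = _as_tensor(a)
    y = out(a.data)
    res = Tensor(y, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(da(g, a.data, y))

    res._backward = backward
    return res


def tanh(a):
    return _unary(a, np.tanh, lambda g, x, y: g * (1.0 - y * y))


def sigmoid(a):
    return _unary(a, lambda x: 1.0 / (1.0 + np.exp(-x)), lambda g, x, y: g * y * (1.0 - y))


def square(a):
    return _unary(a, np.square, lambda g, x, y: g * 2.0 * x)


def exp(a):
    return _unary(a, np.exp, lambda g, x, y: g * y)


def logsumexp(a, axis: int = -1):
    """Stable log-sum-exp along ``axis`` (keeps the reduced axis)."""
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    s = np.exp(a.data - m).sum(axis=axis, keepdims=True)
    y = m + np.log(s)
    res = Tensor(y, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g * np.exp(a.data - y))

    res._backward = backward
    return res


def softmax(a, axis: int = -1):
    """Numerically stable softmax along ``axis``."""
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    res = Tensor(y, requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accumulate(y * (g - dot))

    res._backward = backward
    return res


def concat(tensors, axis: int = -1):
    tensors = [_as_tensor(t) for t in tensors]
    res = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad or t._parents:
                t._accumulate(piece)

    res._backward = backward
    return res


def slice_cols(a, start: int, stop: int):
    """Slice columns [start, stop) of a 2-D tensor."""
    a = _as_tensor(a)
    res = Tensor(a.data[:, start:stop], requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            full = np.zeros_like(a.data)
            full[:, start:stop] = g
            a._accumulate(full)

    res._backward = backward
    return res


def slice_last(a, start: int, stop: int):
    """Slice [start, stop) along the last axis of a tensor of any rank."""
    a = _as_tensor(a)
    res = Tensor(a.data[..., start:stop], requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            full = np.zeros_like(a.data)
            full[..., start:stop] = g
            a._accumulate(full)

    res._backward = backward
    return res


def mean(a):
    a = _as_tensor(a)
    res = Tensor(np.array(a.data.mean()), requires_grad=a.requires_grad, parents=(a,))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(np.full_like(a.data, g / a.data.size))

    res._backward = backward
    return res
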