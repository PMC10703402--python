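"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training losses used in this package (zero-inflated negative binomial
likelihood, adjacency reconstruction, Student-t/KL clustering loss) are all
smooth compositions of dense linear algebra and elementwise maps, so a small
tape-based engine is sufficient: each :class:`Tensor` records the operation
that produced it and a closure that routes the upstream gradient to its
parents.  Gradients are accumulated by a reverse topological sweep from the
scalar loss.

Only the operations the model needs are implemented.  All data is float64.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concat", "logaddexp", "gammaln", "softmax_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray meets a Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        def bw(g, out):
            return (g.T,)

        return Tensor._from_op(self.data.T, (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def bw(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, out):
            return (-g,)

        return Tensor._from_op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bw(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bw(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g, out):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._from_op(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def bw(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._from_op(self.data @ other.data, (self, other), bw)

    # -- elementwise maps -----------------------------------------------------
    def exp(self):
        def bw(g, out):
            return (g * out.data,)

        return Tensor._from_op(np.exp(self.data), (self,), bw)

    def log(self):
        def bw(g, out):
            return (g / self.data,)

        return Tensor._from_op(np.log(self.data), (self,), bw)

    def tanh(self):
        def bw(g, out):
            return (g * (1.0 - out.data**2),)

        return Tensor._from_op(np.tanh(self.data), (self,), bw)

    def relu(self):
        def bw(g, out):
            return (g * (self.data > 0),)

        return Tensor._from_op(np.maximum(self.data, 0.0), (self,), bw)

    def sigmoid(self):
        s = _sp.expit(self.data)

        def bw(g, out):
            return (g * out.data * (1.0 - out.data),)

        return Tensor._from_op(s, (self,), bw)

    def sqrt(self):
        def bw(g, out):
            return (g * 0.5 / out.data,)

        return Tensor._from_op(np.sqrt(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the range."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g, out):
            return (g * mask,)

        return Tensor._from_op(np.clip(self.data, lo, hi), (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


# -- free functions -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g, out):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(datas))
        )

    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise log(exp(a) + exp(b)), stable; grads are softmax weights."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.logaddexp(a.data, b.data)

    def bw(g, out):
        wa = np.exp(a.data - out.data)
        wb = np.exp(b.data - out.data)
        return (_unbroadcast(g * wa, a.shape), _unbroadcast(g * wb, b.shape))

    return Tensor._from_op(out_data, (a, b), bw)


def gammaln(x: Tensor) -> Tensor:
    x = Tensor._lift(x)

    def bw(g, out):
        return (g * _sp.digamma(x.data),)

    return Tensor._from_op(_sp.gammaln(x.data), (x,), bw)


def softmax_rows(x: Tensor) -> Tensor:
    """Softmax along the last axis with the standard max-shift stabilisation."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)

    def bw(g, out):
        dot = (g * out.data).sum(axis=-1, keepdims=True)
        return (out.data * (g - dot),)

    return Tensor._from_op(s, (x,), bw)
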