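"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model code builds its computation graphs from the handful of primitives
defined here (affine maps, elementwise nonlinearities, reductions, concat /
slice).  Gradients are exact up to floating point, which lets the test suite
verify analytic gradients of the full variational objective against central
finite differences.

Everything is float64 and CPU-only; graphs are built eagerly and freed after
each backward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes where the original dimension was 1.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in ``.grad``
    when :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # Topological order by DFS.
        order, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            return (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            return ((self, -g),)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def bwd(g):
            return (
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bwd(g):
            return ((self, g * exponent * self.data ** (exponent - 1)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def bwd(g):
            return (
                (self, g @ other.data.T),
                (other, self.data.T @ g),
            )

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    @property
    def T(self):
        def bwd(g):
            return ((self, g.T),)

        return Tensor(self.data.T, _parents=(self,), _backward=bwd)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            return ((self, g * out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            return ((self, g / self.data),)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            return ((self, g * 0.5 / out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            return ((self, g * mask),)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def logsumexp(self, axis=-1, keepdims=False):
        """Numerically stable log-sum-exp along `axis` (softmax/CE building block)."""
        m = self.data.max(axis=axis, keepdims=True)
        shifted = np.exp(self.data - m)
        s = shifted.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        softmax = shifted / s
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bwd(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, g * softmax),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- shape surgery -----------------------------------------------------

    def __getitem__(self, key):
        out_data = self.data[key]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return ((self, full),)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def reshape(self, *shape):
        def bwd(g):
            return ((self, g.reshape(self.shape)),)

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        pairs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            pairs.append((t, g[tuple(idx)]))
        return tuple(pairs)

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)
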