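"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training path of this package needs gradients through a specific, small
family of computations: affine maps, batch normalization, leaky-ReLU,
softmax/log-softmax of Gumbel-perturbed logits, Gaussian reparameterization
and a handful of reductions.  This module implements a tape-based ``Tensor``
supporting exactly those primitives.  Gradient correctness is checked against
central finite differences in the test suite.

All data are float64.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "concat_rows",
    "leaky_relu",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _result(data, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        tracked = tuple(p for p in parents if p.requires_grad)
        if tracked:
            out.requires_grad = True
            out._parents = tracked
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- autodiff entry point --------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar output through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- shape utilities ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        def bw(g):
            self._accumulate(g.T)
        return Tensor._result(self.data.T, (self,), bw)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))
        return Tensor._result(self.data.reshape(*shape), (self,), bw)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)
        return Tensor._result(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accumulate(-g)
        return Tensor._result(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        return Tensor._result(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))
        return Tensor._result(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))
        return Tensor._result(self.data ** exponent, (self,), bw)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return Tensor._result(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)
        return Tensor._result(out_data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accumulate(g / self.data)
        return Tensor._result(np.log(self.data), (self,), bw)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape))
        return Tensor._result(out_data, (self,), bw)

    def max(self, axis: int) -> "Tensor":
        """Maximum along ``axis``; gradient flows to the winning entries."""
        idx = np.expand_dims(np.argmax(self.data, axis=axis), axis)
        out_data = np.take_along_axis(self.data, idx, axis=axis).squeeze(axis)

        def bw(g):
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, idx, np.expand_dims(g, axis), axis=axis)
            self._accumulate(grad)
        return Tensor._result(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)


def constant(data) -> Tensor:
    """A leaf tensor that never receives gradients."""
    return Tensor(data, requires_grad=False)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, negative_slope)

    def bw(g):
        x._accumulate(g * scale)
    return Tensor._result(x.data * scale, (x,), bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis`` (max-subtraction)."""
    shift = constant(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def concat_rows(tensors: Iterable[Tensor]) -> Tensor:
    """Stack 1-D tensors as the rows of a 2-D tensor."""
    ts = list(tensors)
    data = np.stack([t.data for t in ts], axis=0)

    def bw(g):
        for i, t in enumerate(ts):
            t._accumulate(g[i])
    return Tensor._result(data, ts, bw)
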