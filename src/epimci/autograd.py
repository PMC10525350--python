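"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the package's neural components need
(dense/batched matmul, elementwise nonlinearities, masked reductions, a
sparse-constant matmul for hypergraph propagation, row gathering). Gradients
follow the standard vector-Jacobian-product rules; correctness is checked
against central finite differences in the test suite.

All tensors are float64. Graphs are built eagerly; call :meth:`Tensor.backward`
on a scalar output to populate ``.grad`` on every tensor that requires it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "concat",
    "leaky_relu",
    "relu",
    "sigmoid",
    "softmax",
    "spmm",
    "gather_rows",
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
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _node(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - not needed
            raise TypeError("tensor exponents are not supported")
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return self._node(out_data, (self, other), backward)

    # -- reductions / shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.shape
        return self._node(out_data, (self,), lambda g: (g.reshape(orig),))

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)
        return self._node(out_data, (self,), lambda g: (np.swapaxes(g, a, b),))

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return self._node(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return self._node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._node(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through only inside the range."""
        out_data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)
        return self._node(out_data, (self,), lambda g: (g * inside,))

    # -- autodiff driver -----------------------------------------------------

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
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg


# -- free functions -----------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)
    return Tensor._node(out_data, (x,), lambda g: (g * (x.data > 0.0),))


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    out_data = np.where(x.data > 0.0, x.data, slope * x.data)
    grad_mask = np.where(x.data > 0.0, 1.0, slope)
    return Tensor._node(out_data, (x,), lambda g: (g * grad_mask,))


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._node(out_data, (x,), lambda g: (g * out_data * (1.0 - out_data),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``.

    The row max is treated as a constant, which leaves the gradient unchanged
    because softmax is shift-invariant.
    """
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return (out_data * (g - dot),)

    return Tensor._node(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tensors, backward)


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Multiply a constant sparse matrix by a dense tensor: ``matrix @ x``."""
    matrix = matrix.tocsr()
    out_data = matrix @ x.data
    mt = matrix.T.tocsr()
    return Tensor._node(out_data, (x,), lambda g: (mt @ g,))


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor: output[..., :] = x[index[...], :]."""
    index = np.asarray(index)
    out_data = x.data[index]

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        return (full,)

    return Tensor._node(out_data, (x,), backward)
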