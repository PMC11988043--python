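"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64/float32 ``numpy.ndarray`` together with an
optional gradient buffer and a closure that propagates upstream gradients to
its inputs.  Calling :meth:`Tensor.backward` on a scalar runs a topological
sort of the recorded graph and accumulates ``.grad`` on every tensor that
requires it.  Only the operations the weight-estimation network needs are
implemented; each op states its own backward rule explicitly.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape (:func:`_unbroadcast`).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "maximum", "no_grad", "is_grad_enabled",
           "set_default_dtype", "get_default_dtype"]

_GRAD_ENABLED = [True]
_DEFAULT_DTYPE = [np.dtype(np.float64)]


def set_default_dtype(dtype) -> None:
    """Set the dtype newly created tensors are cast to (float32/float64).

    float64 (the default) is right for verification; float32 roughly halves
    the cost of training runs."""
    dt = np.dtype(dtype)
    if dt not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE[0] = dt


def get_default_dtype():
    return _DEFAULT_DTYPE[0]


class no_grad:
    """Context manager that disables graph recording (evaluation mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "retains_grad")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE[0])
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple = ()
        self.retains_grad = False

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def retain_grad(self):
        self.retains_grad = True
        return self

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _promote(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            is_leaf = node._backward is None
            if is_leaf or node.retains_grad:
                node._accumulate(g)
            if not is_leaf:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._promote(other)
        out_data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._promote(other))

    def __rsub__(self, other):
        return self._promote(other) + (-self)

    def __mul__(self, other):
        other = self._promote(other)
        out_data = self.data * other.data

        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._promote(other) ** -1.0

    def __rtruediv__(self, other):
        return self._promote(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** p

        def backward(g):
            return ((self, g * p * self.data ** (p - 1.0)),)

        return self._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._promote(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            return ((self, g * mask),)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return ((self, g * s * (1.0 - s)),)

        return self._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            return ((self, g * (1.0 - t * t)),)

        return self._make(t, (self,), backward)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def backward(g):
            return ((self, g * e),)

        return self._make(e, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            return ((self, g / self.data),)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            return ((self, g * sign),)

        return self._make(np.abs(self.data), (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            return ((self, g.reshape(old_shape)),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            return ((self, g.transpose(inv)),)

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return ((self, full),)

        return self._make(self.data[idx], (self,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._promote(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return tensors[0]._make(out_data, tuple(tensors), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum; ties send half the gradient to each operand."""
    a, b = Tensor._promote(a), Tensor._promote(b)
    out_data = np.maximum(a.data, b.data)
    wa = np.where(a.data > b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))

    def backward(g):
        return ((a, _unbroadcast(g * wa, a.shape)),
                (b, _unbroadcast(g * (1.0 - wa), b.shape)))

    return a._make(out_data, (a, b), backward)
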