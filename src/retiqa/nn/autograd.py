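"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the package's deep-learning core: a :class:`Tensor` wrapping a
float32 ndarray plus the closed set of differentiable primitives the
quality-assessment network needs (broadcast arithmetic, batched matmul,
2-D convolution and pooling, softmax/sigmoid, reductions, shape moves).
Gradients are accumulated by a topological-order backward sweep, the same
strategy torch uses, at a fraction of the surface area.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "retains_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking ndarray op Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self.retains_grad = False
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def retain_grad(self):
        self.retains_grad = True
        return self

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): _as_array(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None or t.retains_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for p, pg in zip(t._prev, t._backward(g)):
                    if pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    # -- basic info -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data + b.data
        return Tensor._make(
            out_data, (a, b),
            lambda g: tuple(
                _unbroadcast(g, p.data.shape) for p in (a, b) if p.requires_grad
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = a.data * b.data

        def backward(g):
            grads = []
            if a.requires_grad:
                grads.append(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                grads.append(_unbroadcast(g * a.data, b.data.shape))
            return tuple(grads)

        return Tensor._make(out, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = a.data / b.data

        def backward(g):
            grads = []
            if a.requires_grad:
                grads.append(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                grads.append(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
            return tuple(grads)

        return Tensor._make(out, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def pow(self, p: float):
        a = self
        out = a.data ** p
        return Tensor._make(out, (a,), lambda g: (g * p * a.data ** (p - 1),))

    __pow__ = pow

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    # -- matmul -----------------------------------------------------------

    def matmul(self, other):
        other = self._coerce(other)
        a, b = self, other
        out = np.matmul(a.data, b.data)

        def backward(g):
            grads = []
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                grads.append(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                grads.append(_unbroadcast(gb, b.data.shape))
            return tuple(grads)

        return Tensor._make(out, (a, b), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
        return Tensor._make(out, (a,), lambda g: (g * out * (1.0 - out),))

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return ((g - dot) * out,)

        return Tensor._make(out, (a,), backward)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(i % a.data.ndim for i in ax)
                g2 = np.expand_dims(g, tuple(sorted(ax)))
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(out, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i % self.data.ndim]
             for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape moves ------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *perm):
        if len(perm) == 1 and isinstance(perm[0], (tuple, list)):
            perm = tuple(perm[0])
        a = self
        inv = tuple(np.argsort(perm))
        return Tensor._make(
            np.transpose(a.data, perm), (a,), lambda g: (np.transpose(g, inv),)
        )


def concat(tensors, axis: int = 0) -> Tensor:
    """Differentiable concatenation along `axis`."""
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(p for t, p in zip(tensors, parts) if t.requires_grad)

    return Tensor._make(data, tuple(tensors), backward)
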