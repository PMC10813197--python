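"""Minimal reverse-mode automatic differentiation over numpy arrays.

The fusion model needs only a small closed set of differentiable
operations: broadcasted arithmetic, matrix products, the usual
nonlinearities, reductions, indexing/gather, concatenation and a
straight-through clip.  This module provides exactly those on a
``Tensor`` wrapper around ``numpy.ndarray`` with gradient accumulation
and an iterative topological-order backward pass.

The default dtype is float32 (``set_default_dtype`` switches it, which
the gradient-check tests use to run in float64).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float32

#: when False, no computation graph is recorded (fast inference mode)
GRAD_ENABLED = True


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


class no_grad:
    """Context manager disabling graph construction (inference only)."""

    def __enter__(self):
        global GRAD_ENABLED
        self._saved = GRAD_ENABLED
        GRAD_ENABLED = False

    def __exit__(self, *exc):
        global GRAD_ENABLED
        GRAD_ENABLED = self._saved
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()
        self._grad_shared = False

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        # First arrival keeps a reference and marks it shared (the same
        # array may flow to several parents through pass-through ops);
        # a second arrival then allocates instead of mutating in place.
        if self.grad is None:
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- op plumbing ----------------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._grad_shared = False
        out.requires_grad = GRAD_ENABLED and any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        else:
            out._prev = ()
            out._backward = None
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data * b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data / b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * data / b.data, b.data.shape))

        return Tensor._make(data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        a = self
        data = a.data ** p

        def bw(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(data, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(data, (a, b), bw)

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        a = self
        data = np.exp(a.data)

        def bw(g):
            a._accum(g * data)

        return Tensor._make(data, (a,), bw)

    def log(self):
        a = self
        data = np.log(a.data)

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(data, (a,), bw)

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / np.maximum(data, np.finfo(data.dtype).tiny))

        return Tensor._make(data, (a,), bw)

    def tanh(self):
        a = self
        data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - data * data))

        return Tensor._make(data, (a,), bw)

    def sigmoid(self):
        a = self
        # numerically stable two-branch form
        data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data)))).astype(a.data.dtype)

        def bw(g):
            a._accum(g * data * (1.0 - data))

        return Tensor._make(data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0
        data = np.where(mask, a.data, 0.0).astype(a.data.dtype)

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(data, (a,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through on the interior only."""
        a = self
        inside = (a.data > lo) & (a.data < hi)
        data = np.clip(a.data, lo, hi)

        def bw(g):
            a._accum(g * inside)

        return Tensor._make(data, (a,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._make(np.asarray(data, dtype=a.data.dtype), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        data = a.data.reshape(*shape)

        def bw(g):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(data, (a,), bw)

    def transpose(self, *axes):
        a = self
        data = a.data.transpose(*axes)
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(*inv))

        return Tensor._make(data, (a,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        data = np.swapaxes(a.data, ax1, ax2)

        def bw(g):
            a._accum(np.swapaxes(g, ax1, ax2))

        return Tensor._make(data, (a,), bw)

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]
        fancy = isinstance(idx, np.ndarray) or (
            isinstance(idx, tuple) and any(isinstance(i, (np.ndarray, list)) for i in idx)
        )

        def bw(g):
            # accumulate straight into the parent's gradient buffer: a
            # tensor sliced T times then gets one buffer, not T copies
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
                a._grad_shared = False
            elif a._grad_shared:
                a.grad = a.grad.copy()
                a._grad_shared = False
            if fancy:
                np.add.at(a.grad, idx, g)
            else:
                a.grad[idx] += g

        return Tensor._make(data, (a,), bw)


# -- free functions -----------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, ts, bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in ts], axis=axis)

    def bw(g):
        parts = np.split(g, len(ts), axis=axis)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    return Tensor._make(data, ts, bw)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Select by a *constant* boolean condition (no gradient through cond)."""
    ta, tb = Tensor._lift(a), Tensor._lift(b)
    data = np.where(cond, ta.data, tb.data)

    def bw(g):
        if ta.requires_grad:
            ta._accum(_unbroadcast(np.where(cond, g, 0.0), ta.data.shape))
        if tb.requires_grad:
            tb._accum(_unbroadcast(np.where(cond, 0.0, g), tb.data.shape))

    return Tensor._make(data.astype(ta.data.dtype), (ta, tb), bw)


def minimum(a, b) -> Tensor:
    ta, tb = Tensor._lift(a), Tensor._lift(b)
    return where(ta.data <= tb.data, ta, tb)


def maximum(a, b) -> Tensor:
    ta, tb = Tensor._lift(a), Tensor._lift(b)
    return where(ta.data >= tb.data, ta, tb)


def softmax(x: Tensor, axis: int = -1, bias: np.ndarray | None = None) -> Tensor:
    """Softmax with an optional constant additive bias (for masking).

    The row maximum is treated as a constant, which is the standard
    stabilisation and leaves gradients unchanged.
    """
    if bias is not None:
        x = x + bias
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def l2norm(x: Tensor, axis: int = -1, keepdims: bool = True) -> Tensor:
    return (x * x).sum(axis=axis, keepdims=keepdims).sqrt()
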