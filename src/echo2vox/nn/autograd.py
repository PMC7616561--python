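"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar loss accumulates gradients
into every reachable tensor with ``requires_grad``.  The op set is exactly
what the reconstruction networks need: elementwise arithmetic with
broadcasting, reductions, shape ops, stack/concat/slicing, conv / transposed
conv in 2-D and 3-D, relu/sigmoid/softmax and a numerically clamped binary
cross-entropy.
"""

from __future__ import annotations

import numpy as np

from .conv import conv_bwd_data, conv_bwd_weight, conv_forward, conv_out_shape

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "softmax",
    "stack",
    "concat",
    "pad_axis",
    "conv",
    "conv_transpose",
    "binary_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @classmethod
    def _result(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, self._coerce(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._result(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, self._coerce(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            if a.requires_grad:
                a._accumulate(g.reshape(a.shape))

        return Tensor._result(a.data.reshape(shape), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return Tensor._result(a.data[idx], (a,), bwd)

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(ge, a.shape).copy())

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- nonlinearities --------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._result(x.data * mask, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        y = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-x.data)), np.exp(x.data) / (1.0 + np.exp(x.data)))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    return Tensor._result(y, (x,), bwd)


def softmax(x: Tensor, axis: int) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    return Tensor._result(y, (x,), bwd)


# -- structural ops --------------------------------------------------------

def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gi in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gi)

    return Tensor._result(data, tensors, bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accumulate(g[tuple(sl)])
            start += s

    return Tensor._result(data, tensors, bwd)


def pad_axis(x: Tensor, axis: int, before: int, after: int) -> Tensor:
    width = [(0, 0)] * x.data.ndim
    width[axis] = (before, after)

    def bwd(g):
        if x.requires_grad:
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(before, before + x.shape[axis])
            x._accumulate(g[tuple(sl)])

    return Tensor._result(np.pad(x.data, width), (x,), bwd)


# -- convolution -----------------------------------------------------------

def conv(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """Correlation of (B,C,*S) with (F,C,*K); optional bias (F,)."""
    y = conv_forward(x.data, w.data, stride, pad)
    nd = w.data.ndim - 2
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(conv_bwd_data(g, w.data, x.shape[2:], stride, pad))
        if w.requires_grad:
            w._accumulate(conv_bwd_weight(x.data, g, w.shape[2:], stride, pad))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))

    return Tensor._result(y, parents, bwd)


def conv_transpose(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: int = 1,
    pad: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """Transposed convolution; weight layout (C_in, C_out, *K)."""
    nd = w.data.ndim - 2
    kernel = w.shape[2:]
    out_spatial = tuple(
        (s - 1) * stride - 2 * pad + k + output_padding for s, k in zip(x.shape[2:], kernel)
    )
    y = conv_bwd_data(x.data, w.data, out_spatial, stride, pad)
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if x.requires_grad:
            got = conv_forward(g, w.data, stride, pad)
            # forward conv may overshoot when output_padding > 0; it cannot,
            # because conv_out_shape floors — shapes agree by construction
            assert got.shape == x.shape, (got.shape, x.shape)
            x._accumulate(got)
        if w.requires_grad:
            w._accumulate(conv_bwd_weight(g, x.data, kernel, stride, pad))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))

    return Tensor._result(y, parents, bwd)


def binary_cross_entropy(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean voxel-wise BCE of probabilities against a {0,1} target."""
    t = np.asarray(target, dtype=np.float64)
    p = np.clip(pred.data, eps, 1.0 - eps)
    loss = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()

    def bwd(g):
        if pred.requires_grad:
            inside = (pred.data > eps) & (pred.data < 1.0 - eps)
            dp = -(t / p - (1.0 - t) / (1.0 - p)) / p.size
            pred._accumulate(g * dp * inside)

    return Tensor._result(loss, (pred,), bwd)
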