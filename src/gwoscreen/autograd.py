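"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order accumulating gradients.  The op set is exactly what the segmentation
and capsule networks in this package need: broadcast arithmetic, matmul
(with batch broadcasting), elementwise nonlinearities, reductions, shape
ops, 2-D convolution, 2x2 max pooling, nearest-neighbour upsampling and
channel concatenation.  Everything is float32 for speed on CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "upsample2x",
    "relu",
    "sigmoid",
    "softmax",
]

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = _as_array(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        out._parents = (self, other)
        a, b = self.data, other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- elementwise ------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        out._parents = (self,)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        out._parents = (self,)
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def maximum(self, other: float):
        """Elementwise max with a scalar (hinge building block)."""
        out = Tensor(np.maximum(self.data, other), self.requires_grad)
        out._parents = (self,)
        mask = self.data > other

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    # -- reductions and shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        out._parents = (self,)
        shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(DTYPE))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).astype(DTYPE))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        out._parents = (self,)
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        out._parents = (self,)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# functional ops


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad)
    out._parents = (x,)
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    out = Tensor(s, x.requires_grad)
    out._parents = (x,)

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    Forward uses the log-sum-exp form; the gradient is the exact
    (sigmoid(l) - y) / n, which never saturates the way a clipped
    probability would.
    """
    l = logits.data
    y = np.asarray(targets, dtype=DTYPE)
    loss = np.maximum(l, 0) - l * y + np.log1p(np.exp(-np.abs(l)))
    out = Tensor(loss.mean(), logits.requires_grad)
    out._parents = (logits,)
    n = l.size

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(l, -60.0, 60.0)))
            logits._accumulate((g * (s - y) / n).astype(DTYPE))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax (max-shift is treated as a constant)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req)
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,).
    """
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    kh, kw = w.data.shape[2], w.data.shape[3]
    win = sliding_window_view(xd, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, kh, kw)
    out_data = np.einsum("nchwkl,ockl->nohw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(out_data, req)
    out._parents = (x, w) if b is None else (x, w, b)
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("nohw,nchwkl->ockl", g, win, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    # contribution of kernel tap (i, j)
                    gxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = bw
    return out


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = r.max(axis=(3, 5))
    out = Tensor(out_data, x.requires_grad)
    out._parents = (x,)
    mask = r == out_data[:, :, :, None, :, None]

    def bw(g):
        if x.requires_grad:
            gr = mask * g[:, :, :, None, :, None]
            x._accumulate(gr.reshape(n, c, h, w))

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                 x.requires_grad)
    out._parents = (x,)
    n, c, h, w = x.data.shape

    def bw(g):
        if x.requires_grad:
            gr = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accumulate(gr)

    out._backward = bw
    return out
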