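"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the convolutional encoders and
the feature-matching network: broadcast-aware arithmetic, matmul, 2-D
convolution / max-pooling via im2col, reductions, elementwise nonlinearities,
bilinear resizing expressed as fixed interpolation matrices, and a fused
softmax cross-entropy. All computation is float32 by default and fully
deterministic for a given input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "relu",
    "sigmoid",
    "softplus",
    "conv2d",
    "max_pool2d",
    "resize_bilinear",
    "cross_entropy",
    "interp_matrix",
]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to produce `shape`."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._prev = _prev
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def build(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g2, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad=False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


# ------------------------------------------------------------- nonlinearities
def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1 - s))

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    # numerically stable log(1 + e^x)
    d = x.data
    sp = np.maximum(d, 0) + np.log1p(np.exp(-np.abs(d)))
    out = Tensor(sp, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g / (1.0 + np.exp(-d)))

    out._backward = bw
    return out


# ----------------------------------------------------------------- im2col ops
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, C, kh, kw, OH, OW),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(B, C * kh * kw, OH * OW)
    return cols, OH, OW


def _col2im(cols: np.ndarray, x_shape, kh, kw, stride, pad):
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    cols6 = cols.reshape(B, C, kh, kw, OH, OW)
    xp = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += cols6[:, :, i, j]
    if pad:
        return xp[:, :, pad : pad + H, pad : pad + W]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, via im2col."""
    F, C, kh, kw = w.data.shape
    if x.data.shape[1] != C:
        raise ValueError(f"conv2d: expected {C} input channels, got {x.data.shape[1]}")
    cols, OH, OW = _im2col(x.data, kh, kw, stride, padding)
    W2 = w.data.reshape(F, C * kh * kw)
    out_data = np.matmul(W2, cols).reshape(x.data.shape[0], F, OH, OW)
    if b is not None:
        out_data = out_data + b.data.reshape(1, F, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, req, prev)

    def bw(g):
        B = x.data.shape[0]
        g2 = g.reshape(B, F, OH * OW)
        if w.requires_grad:
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(W2.T, g2)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding))

    out._backward = bw
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    B, C, H, W = x.data.shape
    xr = x.data.reshape(B * C, 1, H, W)
    # pad with -inf so padding never wins the max
    xp = np.pad(xr, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf) if padding else xr
    cols, OH, OW = _im2col(xp, kernel, kernel, stride, 0)
    idx = np.argmax(cols, axis=1)
    mx = np.take_along_axis(cols, idx[:, None, :], axis=1)[:, 0, :]
    out = Tensor(mx.reshape(B, C, OH, OW), x.requires_grad, (x,))

    def bw(g):
        if not x.requires_grad:
            return
        g2 = g.reshape(B * C, OH * OW)
        gcols = np.zeros_like(cols)
        np.put_along_axis(gcols, idx[:, None, :], g2[:, None, :], axis=1)
        gx = _col2im(gcols, xp.shape, kernel, kernel, stride, 0)
        if padding:
            gx = gx[:, :, padding : padding + H, padding : padding + W]
        x._accumulate(gx.reshape(B, C, H, W))

    out._backward = bw
    return out


# ----------------------------------------------------------- bilinear resizing
def interp_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """Linear-interpolation matrix A (n_out x n_in) with endpoint alignment."""
    A = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    pos = np.array([(n_in - 1) / 2.0]) if n_out == 1 else np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = pos - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), lo + 1] += frac
    return A


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor."""
    B, C, H, W = x.data.shape
    Ah = interp_matrix(out_h, H, dtype=x.data.dtype)
    Aw = interp_matrix(out_w, W, dtype=x.data.dtype)
    y = np.matmul(np.matmul(Ah, x.data), Aw.T)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(Ah.T, g), Aw))

    out._backward = bw
    return out


# -------------------------------------------------------------- cross entropy
def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch; labels are integer classes."""
    z = logits.data
    labels = np.asarray(labels)
    if z.shape[0] != labels.shape[0]:
        raise ValueError("cross_entropy: batch size mismatch")
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = (z - zmax) - np.log(sez)
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(np.asarray(loss, dtype=z.dtype), logits.requires_grad, (logits,))

    def bw(g):
        if logits.requires_grad:
            grad = ez / sez
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(grad * (g / n))

    out._backward = bw
    return out
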