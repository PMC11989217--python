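"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the leaf-withering classifier needs:
elementwise arithmetic with broadcasting, matmul, reductions, shape ops,
slicing/concatenation, the usual activations and a grouped 2-D convolution
(the single heavy primitive; forward via strided window views, backward via
a k*k scatter-add). Everything runs in float32.

This is a training engine for small CPU models, not a general framework:
no in-place ops, no higher-order gradients, single device.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "relu",
    "sigmoid",
    "silu",
    "hard_swish",
    "softmax",
    "log_softmax",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    return a.astype(np.float32) if a.dtype != np.float32 else a


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs here can be thousands deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else _as_f32(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = _node(self.data + other.data, (self, other))

        def bw():
            _accum(self, _unbroadcast(out.grad, self.data.shape))
            _accum(other, _unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda: _accum(self, -out.grad)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = _node(self.data * other.data, (self, other))

        def bw():
            _accum(self, _unbroadcast(out.grad * other.data, self.data.shape))
            _accum(other, _unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = _node(self.data / other.data, (self, other))

        def bw():
            _accum(self, _unbroadcast(out.grad / other.data, self.data.shape))
            _accum(
                other,
                _unbroadcast(
                    -out.grad * self.data / (other.data * other.data),
                    other.data.shape,
                ),
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))

        def bw():
            _accum(self, out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = _node(self.data @ other.data, (self, other))

        def bw():
            _accum(self, out.grad @ other.data.T)
            _accum(other, self.data.T @ out.grad)

        out._backward = bw
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out = _node(np.exp(self.data), (self,))
        out._backward = lambda: _accum(self, out.grad * out.data)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda: _accum(self, out.grad / self.data)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = _node(self.data.reshape(shape), (self,))
        out._backward = lambda: _accum(self, out.grad.reshape(src))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        out._backward = lambda: _accum(self, out.grad.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            _accum(self, g)

        out._backward = bw
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# -- joins ---------------------------------------------------------------
def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, out.grad[tuple(sl)])

    out._backward = bw
    return out


# -- convolution ---------------------------------------------------------
def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout.

    ``w`` has shape (C_out, C_in/groups, kh, kw); both C_in and C_out must be
    divisible by ``groups``.
    """
    B, Cin, H, W = x.data.shape
    Cout, Cing, kh, kw = w.data.shape
    g = groups
    if Cin % g or Cout % g or Cing != Cin // g:
        raise ValueError(
            f"channel counts ({Cin}->{Cout}) not divisible into {g} groups"
        )
    s, p = stride, padding
    if H + 2 * p < kh or W + 2 * p < kw:
        raise ValueError("input spatial dims smaller than kernel")

    if kh == 1 and kw == 1 and p == 0:
        # fast path: 1x1 convolution is a per-pixel channel mixing
        xs = x.data[:, :, ::s, ::s]
        Ho, Wo = xs.shape[2], xs.shape[3]
        xsr = xs.reshape(B, g, Cing, Ho, Wo)
        wr = w.data.reshape(g, Cout // g, Cing)
        out_data = np.einsum("bgchw,goc->bgohw", xsr, wr, optimize=True)
        out_data = out_data.reshape(B, Cout, Ho, Wo)
        if b is not None:
            out_data = out_data + b.data.reshape(1, -1, 1, 1)
        parents = (x, w) if b is None else (x, w, b)
        out = _node(out_data, parents)

        def bw1():
            go = out.grad.reshape(B, g, Cout // g, Ho, Wo)
            if w.requires_grad:
                dw = np.einsum("bgchw,bgohw->goc", xsr, go, optimize=True)
                _accum(w, dw.reshape(Cout, Cing, 1, 1))
            if b is not None and b.requires_grad:
                _accum(b, out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxs = np.einsum("bgohw,goc->bgchw", go, wr, optimize=True)
                if s == 1:
                    _accum(x, dxs.reshape(B, Cin, Ho, Wo))
                else:
                    dx = np.zeros_like(x.data)
                    dx[:, :, ::s, ::s] = dxs.reshape(B, Cin, Ho, Wo)
                    _accum(x, dx)

        out._backward = bw1
        return out

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # one contiguous copy of the windows, shared by forward and backward
    winr = np.ascontiguousarray(win).reshape(B, g, Cing, Ho, Wo, kh, kw)
    wr = w.data.reshape(g, Cout // g, Cing, kh, kw)
    out_data = np.einsum("bgchwij,gocij->bgohw", winr, wr, optimize=True)
    out_data = out_data.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(out_data, parents)

    def bw():
        go = out.grad.reshape(B, g, Cout // g, Ho, Wo)
        if w.requires_grad:
            dw = np.einsum("bgchwij,bgohw->gocij", winr, go, optimize=True)
            _accum(w, dw.reshape(Cout, Cing, kh, kw))
        if b is not None and b.requires_grad:
            _accum(b, out.grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dwin = np.einsum("bgohw,gocij->bgchwij", go, wr, optimize=True)
            dwin = dwin.reshape(B, Cin, Ho, Wo, kh, kw)
            dxp = np.zeros_like(xp) if p else np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += dwin[
                        :, :, :, :, i, j
                    ]
            _accum(x, dxp[:, :, p : p + H, p : p + W] if p else dxp)

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise average pooling expressed as a fixed-weight convolution."""
    c = x.data.shape[1]
    w = Tensor(np.full((c, 1, kernel, kernel), 1.0 / (kernel * kernel)))
    return conv2d(x, w, stride=stride, padding=padding, groups=c)


# -- fused layers --------------------------------------------------------
def batchnorm2d_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch norm over NCHW; returns (y, mean, var).

    mean/var are the biased batch statistics as plain arrays (for running
    averages). Backward uses the closed-form batch-norm gradient.
    """
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    var = x.data.var(axis=(0, 2, 3), keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd
    c = x.data.shape[1]
    y = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
    out = _node(y, (x, gamma, beta))
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bw():
        go = out.grad
        if gamma.requires_grad:
            _accum(gamma, (go * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, go.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = go * gamma.data.reshape(1, c, 1, 1)
            t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            _accum(x, invstd / n * (n * dxhat - t1 - xhat * t2))

    out._backward = bw
    return out, mu.reshape(-1), var.reshape(-1)


def scale_shift(x: Tensor, scale: np.ndarray, shift: np.ndarray) -> Tensor:
    """y = x * scale + shift with constant per-channel arrays (NCHW)."""
    c = x.data.shape[1]
    s = scale.reshape(1, c, 1, 1)
    out = _node(x.data * s + shift.reshape(1, c, 1, 1), (x,))
    out._backward = lambda: _accum(x, out.grad * s)
    return out


# -- activations ---------------------------------------------------------
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _node(np.where(mask, x.data, 0.0), (x,))
    out._backward = lambda: _accum(x, out.grad * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(s, (x,))
    out._backward = lambda: _accum(x, out.grad * s * (1.0 - s))
    return out


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(x.data * s, (x,))
    out._backward = lambda: _accum(x, out.grad * s * (1.0 + x.data * (1.0 - s)))
    return out


def hard_swish(x: Tensor) -> Tensor:
    # x * clip(x + 3, 0, 6) / 6
    xd = x.data
    out = _node(xd * np.clip(xd + 3.0, 0.0, 6.0) / 6.0, (x,))

    def bw():
        d = np.where(xd <= -3.0, 0.0, np.where(xd >= 3.0, 1.0, (2.0 * xd + 3.0) / 6.0))
        _accum(x, out.grad * d.astype(np.float32))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    e = np.exp(x.data - np.max(x.data, axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (x,))

    def bw():
        go = out.grad
        _accum(x, y * (go - (go * y).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int) -> Tensor:
    shift = x - np.max(x.data, axis=axis, keepdims=True)
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()
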