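"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for each derived value,
its parents and a backward closure.  :meth:`Tensor.backward` runs the tape in
reverse topological order and accumulates gradients into every tensor with
``requires_grad=True``.  Only the operations the segmentation network needs
are provided; each op hand-codes its vector-Jacobian product, and every one
of them is covered by finite-difference checks in the test suite.

Convolutions are computed by im2col + matmul; the fold (col2im) in the
backward pass is the 3x3-offset scatter-add, which is exact and vectorised.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "add", "mul", "scale", "matmul", "linear",
    "conv2d", "conv1d_channels", "prelu", "relu", "sigmoid", "softmax_channel",
    "maxpool2x2", "upsample_bilinear", "concat_channels", "gap2d",
    "channel_scale", "gather_pixels", "reshape",
]


class Tensor:
    """An array plus the bookkeeping needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype.kind in "iub":
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data, dtype=np.result_type(self.data, np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- arithmetic -------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return _node(a.data * c, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = matmul(x, w)
    return out if b is None else add(out, b)


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    old = x.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(old))

    return _node(x.data.reshape(shape), (x,), backward)


# -- convolutions -----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1) -> Tensor:
    """2-D correlation, stride 1.  ``x``: [N,C,H,W]; ``w``: [O,C,kh,kw]."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh, ow = h + 2 * padding - kh + 1, wd + 2 * padding - kw + 1
    # cols[n, i, j, c, u, v] = xp[n, c, i+u, j+v]
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3)).transpose(0, 2, 3, 1, 4, 5)
    cols2 = np.ascontiguousarray(cols).reshape(n * oh * ow, c * kh * kw)
    wflat = w.data.reshape(o, -1)
    out = cols2 @ wflat.T
    if b is not None:
        b = as_tensor(b)
        out = out + b.data
    out = out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * oh * ow, o)
        if w.requires_grad:
            w._accumulate((gm.T @ cols2).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wflat).reshape(n, oh, ow, c, kh, kw)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u:u + oh, v:v + ow] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv1d_channels(x: Tensor, w: Tensor) -> Tensor:
    """Bias-free 1-D convolution along the channel axis of ``x`` [N,C].

    Zero padding keeps the length; this is the channel-mixing step of
    efficient channel attention.
    """
    x, w = as_tensor(x), as_tensor(w)
    k = w.shape[0]
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    p = k // 2
    n, c = x.shape
    xp = np.pad(x.data, ((0, 0), (p, p)))
    out = np.zeros_like(x.data)
    for d in range(k):
        out += w.data[d] * xp[:, d:d + c]

    def backward(g):
        if w.requires_grad:
            dw = np.array([(g * xp[:, d:d + c]).sum() for d in range(k)])
            w._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for d in range(k):
                dxp[:, d:d + c] += w.data[d] * g
            x._accumulate(dxp[:, p:p + c])

    return _node(out, (x, w), backward)


# -- activations ------------------------------------------------------------

def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU with one learnable slope per channel.

    ``slope`` has shape [C]; the channel axis is axis 1 for 4-D inputs and the
    last axis for 2-D inputs.
    """
    x, slope = as_tensor(x), as_tensor(slope)
    if x.data.ndim == 4:
        s = slope.data[None, :, None, None]
        red_axes = (0, 2, 3)
    elif x.data.ndim == 2:
        s = slope.data[None, :]
        red_axes = (0,)
    else:
        raise ValueError("prelu expects a 2-D or 4-D input")
    neg = x.data <= 0
    out = np.where(neg, s * x.data, x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.where(neg, s * g, g))
        if slope.requires_grad:
            slope._accumulate((g * np.where(neg, x.data, 0.0)).sum(axis=red_axes))

    return _node(out, (x, slope), backward)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    pos = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * pos)

    return _node(np.where(pos, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    return _node(y, (x,), backward)


def softmax_channel(x: Tensor) -> Tensor:
    """Softmax over axis 1 of a [N,C,...] tensor."""
    x = as_tensor(x)
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=1, keepdims=True)
            x._accumulate(y * (g - dot))

    return _node(y, (x,), backward)


# -- spatial ops ------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = np.ascontiguousarray(r).reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
            dx = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(np.ascontiguousarray(dx).reshape(n, c, h, w))

    return _node(out, (x,), backward)


def _resize_axis(n_in: int, n_out: int):
    """Pixel-centre bilinear sampling grid for one axis (corners not aligned)."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i0 = np.minimum(i0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    return i0, i1, frac


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation operator [n_out, n_in]."""
    i0, i1, frac = _resize_axis(n_in, n_out)
    mat = np.zeros((n_out, n_in))
    rows = np.arange(n_out)
    np.add.at(mat, (rows, i0), 1.0 - frac)
    np.add.at(mat, (rows, i1), frac)
    return mat.astype(dtype)


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of a [N,C,h,w] tensor with pixel-centre alignment.

    Separable: out = Wy @ x @ Wx^T with the per-axis interpolation operators,
    so the backward pass is the exact transpose, dx = Wy^T @ g @ Wx.
    """
    x = as_tensor(x)
    n, c, h, w = x.shape
    wy = _interp_matrix(h, out_h, x.data.dtype)
    wx = _interp_matrix(w, out_w, x.data.dtype)
    out = np.matmul(np.matmul(wy, x.data), wx.T)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(wy.T, g), wx))

    return _node(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    ca = a.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _node(np.concatenate([a.data, b.data], axis=1), (a, b), backward)


def gap2d(x: Tensor) -> Tensor:
    """Global average pooling: [N,C,H,W] -> [N,C]."""
    x = as_tensor(x)
    n, c, h, w = x.shape

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g[:, :, None, None], x.shape) / (h * w))

    return _node(x.data.mean(axis=(2, 3)), (x,), backward)


def channel_scale(x: Tensor, w: Tensor) -> Tensor:
    """Multiply each channel of [N,C,H,W] ``x`` by a per-channel weight [N,C]."""
    x, w = as_tensor(x), as_tensor(w)
    wb = w.data[:, :, None, None]

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * wb)
        if w.requires_grad:
            w._accumulate((g * x.data).sum(axis=(2, 3)))

    return _node(x.data * wb, (x, w), backward)


def gather_pixels(x: Tensor, indices: np.ndarray) -> Tensor:
    """Gather per-image pixel vectors: [N,C,H,W] + [N,k] flat indices -> [N,k,C]."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    idx = np.asarray(indices)
    if idx.min() < 0 or idx.max() >= h * w:
        raise IndexError("pixel index out of range")
    flat = x.data.reshape(n, c, h * w)
    out = np.take_along_axis(flat, idx[:, None, :], axis=2).transpose(0, 2, 1)

    def backward(g):
        if x.requires_grad:
            dflat = np.zeros((n, c, h * w), dtype=g.dtype)
            ni = np.arange(n)[:, None, None]
            ci = np.arange(c)[None, :, None]
            np.add.at(dflat, (ni, ci, idx[:, None, :]), g.transpose(0, 2, 1))
            x._accumulate(dflat.reshape(n, c, h, w))

    return _node(out, (x,), backward)
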