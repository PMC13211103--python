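"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the attention block, the contrastive
heads, the reconstruction loss and the tiny detector.  It implements the
small set of differentiable operations those components need (broadcasted
arithmetic, matmul, 2-D convolution via window views, pooling reductions,
bilinear RoI pooling, nearest-neighbour upsampling) with float64 arrays
throughout.  Gradients are accumulated by a single backward sweep over a
topologically sorted tape.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- autodiff engine -------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        _accum(self, np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _make(data: np.ndarray, parents, backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# -- elementwise --------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def power(a, p: float):
    a = as_tensor(a)
    data = a.data ** p

    def bw(g):
        if a.requires_grad:
            _accum(a, g * p * a.data ** (p - 1.0))

    return _make(data, (a,), bw)


def exp(a):
    a = as_tensor(a)
    data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            _accum(a, g * data)

    return _make(data, (a,), bw)


def log(a):
    a = as_tensor(a)
    data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            _accum(a, g / a.data)

    return _make(data, (a,), bw)


def sigmoid(a):
    a = as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        if a.requires_grad:
            _accum(a, g * data * (1.0 - data))

    return _make(data, (a,), bw)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def bw(g):
        if a.requires_grad:
            _accum(a, g * mask)

    return _make(data, (a,), bw)


def clip(a, lo: float, hi: float):
    """Clamp values; gradient is passed only inside the interval."""
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bw(g):
        if a.requires_grad:
            _accum(a, g * mask)

    return _make(data, (a,), bw)


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = np.maximum(a.data, b.data)
    ga = np.where(a.data > b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * ga, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * (1.0 - ga), b.data.shape))

    return _make(data, (a, b), bw)


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = np.minimum(a.data, b.data)
    ga = np.where(a.data < b.data, 1.0, np.where(a.data == b.data, 0.5, 0.0))

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * ga, a.data.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * (1.0 - ga), b.data.shape))

    return _make(data, (a, b), bw)


# -- reductions ---------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(a, axis=None, keepdims=False):
    """Max reduction; the gradient is split equally among tied argmaxes."""
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == data).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)
    out = data if keepdims or axis is None else np.squeeze(
        data, axis=axis if isinstance(axis, tuple) else (axis,)
    )
    if axis is None and not keepdims:
        out = out.reshape(())

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            _accum(a, mask * g)
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(a, mask * g)

    return _make(out, (a,), bw)


# -- shape ops ----------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            _accum(a, g.reshape(a.data.shape))

    return _make(data, (a,), bw)


def transpose(a, axes=None):
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def bw(g):
        if a.requires_grad:
            _accum(a, g.transpose(inv))

    return _make(data, (a,), bw)


def getitem(a, idx):
    a = as_tensor(a)
    data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            _accum(a, full)

    return _make(data, (a,), bw)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, g[tuple(sl)])

    return _make(data, tuple(tensors), bw)


# -- linear algebra -----------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            _accum(a, g @ b.data.T)
        if b.requires_grad:
            _accum(b, a.data.T @ g)

    return _make(data, (a, b), bw)


# -- conv / spatial -----------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding=(0, 0)):
    """2-D convolution (cross-correlation), zero padded.

    x: (B,C,H,W); w: (O,C,kh,kw); b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    O, C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C} vs kernel {C2}")
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    out = np.einsum("bcijuv,ocuv->boij", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    oh, ow = out.shape[2], out.shape[3]

    def bw(g):
        if w.requires_grad:
            _accum(w, np.einsum("bcijuv,boij->ocuv", win, g, optimize=True))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    contrib = np.einsum("boij,oc->bcij", g, w.data[:, :, u, v],
                                        optimize=True)
                    gxp[:, :, u:u + oh * stride:stride,
                        v:v + ow * stride:stride] += contrib
            _accum(x, gxp[:, :, ph:ph + H, pw:pw + W])

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out, parents, bw)


def upsample2(x):
    """Nearest-neighbour 2x spatial upsampling."""
    x = as_tensor(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = x.data.shape

    def bw(g):
        if x.requires_grad:
            _accum(x, g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(data, (x,), bw)


def roi_align(x, rois: np.ndarray, out_size: int):
    """Bilinear RoI pooling with one sample at each bin centre.

    x: (B,C,H,W); rois: (N,5) rows of (batch_index, x1, y1, x2, y2) with
    box coordinates normalized to [0,1].  Returns (N,C,out_size,out_size).
    Sample coordinates follow the half-pixel convention
    (feature coordinate = normalized * size - 0.5), clamped to the border.
    """
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    rois = np.asarray(rois, dtype=np.float64)
    N = rois.shape[0]
    r = out_size
    out = np.empty((N, C, r, r))
    caches = []
    bins = (np.arange(r) + 0.5) / r
    for n in range(N):
        bi = int(rois[n, 0])
        x1, y1, x2, y2 = rois[n, 1:]
        if x2 <= x1 or y2 <= y1:
            raise ValueError("degenerate RoI (zero area)")
        sx = (x1 + bins * (x2 - x1)) * W - 0.5
        sy = (y1 + bins * (y2 - y1)) * H - 0.5
        sx = np.clip(sx, 0.0, W - 1.0)
        sy = np.clip(sy, 0.0, H - 1.0)
        x0 = np.floor(sx).astype(int)
        y0 = np.floor(sy).astype(int)
        x1i = np.minimum(x0 + 1, W - 1)
        y1i = np.minimum(y0 + 1, H - 1)
        fx = sx - x0
        fy = sy - y0
        fm = x.data[bi]
        top = fm[:, y0][:, :, x0] * (1 - fx) + fm[:, y0][:, :, x1i] * fx
        bot = fm[:, y1i][:, :, x0] * (1 - fx) + fm[:, y1i][:, :, x1i] * fx
        out[n] = top * (1 - fy)[:, None] + bot * (fy)[:, None]
        caches.append((bi, x0, y0, x1i, y1i, fx, fy))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        for n, (bi, x0, y0, x1i, y1i, fx, fy) in enumerate(caches):
            gn = g[n]  # (C, r, r)
            wy0 = (1 - fy)[:, None]
            wy1 = fy[:, None]
            wx0 = (1 - fx)[None, :]
            wx1 = fx[None, :]
            yy0 = np.repeat(y0, r)
            yy1 = np.repeat(y1i, r)
            xx0 = np.tile(x0, r)
            xx1 = np.tile(x1i, r)
            for wy, yy in ((wy0, yy0), (wy1, yy1)):
                for wx, xx in ((wx0, xx0), (wx1, xx1)):
                    vals = (gn * wy * wx).reshape(C, -1)
                    np.add.at(gx[bi], (slice(None), yy, xx), vals)
        _accum(x, gx)

    return _make(out, (x,), bw)
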