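"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the primitives the model needs:
broadcast arithmetic, (batched) matmul, stride-1 grouped/dilated convolution,
patchifying and non-overlapping transposed convolution, 2x2 max pooling,
adaptive average pooling, bilinear interpolation, normalisation, softmax and
the usual pointwise activations.  All arithmetic is float64; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data.copy()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad += g


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------
# elementwise / reductions
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _acc(a, _unbroadcast(g, a.shape))
        _acc(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _acc(a, _unbroadcast(g * b.data, a.shape))
        _acc(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bwd)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def bwd(g):
        _acc(a, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), bwd)


def texp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        _acc(a, g * out_data)

    return _make(out_data, (a,), bwd)


def tlog(a) -> Tensor:
    a = as_tensor(a)

    def bwd(g):
        _acc(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _acc(a, np.broadcast_to(gg, a.shape).copy())

    return _make(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclipped entries."""
    a = as_tensor(a)
    mask = (a.data >= lo) & (a.data <= hi)

    def bwd(g):
        _acc(a, g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), bwd)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def bwd(g):
        _acc(a, g * mask)

    return _make(a.data * mask, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _acc(a, g * s * (1.0 - s))

    return _make(s, (a,), bwd)


def gelu(a) -> Tensor:
    """Exact (erf-based) GELU."""
    a = as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))

    def bwd(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        _acc(a, g * (cdf + x * pdf))

    return _make(x * cdf, (a,), bwd)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        _acc(a, s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return _make(s, (a,), bwd)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    sm = np.exp(out_data)

    def bwd(g):
        _acc(a, g - sm * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), bwd)


# ---------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------

def reshape(a, *shape) -> Tensor:
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])

    def bwd(g):
        _acc(a, g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), bwd)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def bwd(g):
        _acc(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bwd)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def bwd(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g  # pure-slice indexing: no duplicate positions
            _acc(a, full)

    return _make(a.data[idx], (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _acc(t, piece)

    return _make(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)


def pad2d(a, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the last two axes of an NCHW tensor."""
    a = as_tensor(a)
    if pad_h == 0 and pad_w == 0:
        return a
    widths = [(0, 0)] * (a.ndim - 2) + [(0, pad_h), (0, pad_w)]
    H, W = a.shape[-2], a.shape[-1]

    def bwd(g):
        _acc(a, g[..., :H, :W])

    return _make(np.pad(a.data, widths), (a,), bwd)


# ---------------------------------------------------------------------
# matmul
# ---------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        if a.requires_grad:
            _acc(a, _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.shape))
        if b.requires_grad:
            _acc(b, _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape))

    return _make(np.matmul(a.data, b.data), (a, b), bwd)


# ---------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------

def normalize(a, axes, eps: float = 1e-6) -> Tensor:
    """(x - mean) / sqrt(var + eps) over ``axes``; affine applied by caller."""
    a = as_tensor(a)
    axes = tuple(axes)
    mu = a.data.mean(axis=axes, keepdims=True)
    var = a.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (a.data - mu) * inv

    def bwd(g):
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        _acc(a, inv * (g - gm - xhat * gxm))

    return _make(xhat, (a,), bwd)


# ---------------------------------------------------------------------
# convolution / pooling / interpolation
# ---------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, dil: int, hout: int, wout: int):
    # stride-1 column matrix: (N, C, kh*kw, hout*wout)
    i0 = np.repeat(np.arange(kh) * dil, kw)
    j0 = np.tile(np.arange(kw) * dil, kh)
    i1 = np.repeat(np.arange(hout), wout)
    j1 = np.tile(np.arange(wout), hout)
    rows = i0[:, None] + i1[None, :]
    cols = j0[:, None] + j1[None, :]
    return xp[:, :, rows, cols]


def _conv2d_raw(xd: np.ndarray, wd: np.ndarray, padding: int, dilation: int,
                groups: int):
    """Stride-1 grouped convolution on raw arrays; returns (out, col)."""
    n, cin, h, w = xd.shape
    cout, cin_g, kh, kw = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hout = h + 2 * padding - dilation * (kh - 1)
    wout = w + 2 * padding - dilation * (kw - 1)
    col = _im2col(xp, kh, kw, dilation, hout, wout)  # (n, cin, khkw, L)
    col = col.reshape(n, groups, cin_g * kh * kw, hout * wout)
    wg = wd.reshape(groups, cout // groups, cin_g * kh * kw)
    out = np.einsum("gok,ngkl->ngol", wg, col, optimize=True)
    return out.reshape(n, cout, hout, wout), col


def conv2d(x, w, b=None, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout."""
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wdt = x.shape
    cout, cin_g, kh, kw = w.shape
    out_data, col = _conv2d_raw(x.data, w.data, padding, dilation, groups)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    hout, wout = out_data.shape[2], out_data.shape[3]

    def bwd(g):
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)))
        gg = g.reshape(n, groups, cout // groups, hout * wout)
        if w.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gg, col, optimize=True)
            _acc(w, gw.reshape(w.shape))
        if x.requires_grad:
            # full correlation of g with channel-swapped, spatially flipped w
            wf = w.data[:, :, ::-1, ::-1]
            wf = wf.reshape(groups, cout // groups, cin_g, kh, kw)
            wf = wf.transpose(0, 2, 1, 3, 4).reshape(cin, cout // groups, kh, kw)
            pad_b = dilation * (kh - 1) - padding
            if pad_b < 0:
                raise ValueError("unsupported conv geometry for backward")
            gx, _ = _conv2d_raw(g, wf, pad_b, dilation, groups)
            _acc(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def conv2d_patchify(x, w, b=None) -> Tensor:
    """Non-overlapping convolution with stride == kernel (patch embedding)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    d, c2, p, p2 = w.shape
    assert c == c2 and p == p2 and h % p == 0 and wd % p == 0
    hg, wg = h // p, wd // p
    xr = x.data.reshape(n, c, hg, p, wg, p)
    out_data = np.einsum("nchpwq,dcpq->ndhw", xr, w.data, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            _acc(w, np.einsum("ndhw,nchpwq->dcpq", g, xr, optimize=True))
        if x.requires_grad:
            gx = np.einsum("ndhw,dcpq->nchpwq", g, w.data, optimize=True)
            _acc(x, gx.reshape(n, c, h, wd))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def conv_transpose2d(x, w, b=None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (no overlap).

    ``w`` has shape (C_in, C_out, k, k).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wd = x.shape
    cin2, cout, k, k2 = w.shape
    assert cin == cin2 and k == k2 == stride
    out_data = np.einsum("nchw,cdpq->ndhpwq", x.data, w.data, optimize=True)
    out_data = out_data.reshape(n, cout, h * k, wd * k)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    def bwd(g):
        gr = g.reshape(n, cout, h, k, wd, k)
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            _acc(w, np.einsum("ndhpwq,nchw->cdpq", gr, x.data, optimize=True))
        if x.requires_grad:
            _acc(x, np.einsum("ndhpwq,cdpq->nchw", gr, w.data, optimize=True))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def maxpool2d(x, k: int = 2) -> Tensor:
    """Max pooling with kernel == stride == k (spatial dims divisible by k)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    assert h % k == 0 and w % k == 0
    xr = x.data.reshape(n, c, h // k, k, w // k, k)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, arg[..., None], g[..., None], axis=-1)
        gf = gf.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        _acc(x, gf.reshape(n, c, h, w))

    return _make(out_data, (x,), bwd)


def adaptive_avg_pool2d(x, out_hw) -> Tensor:
    """Adaptive average pooling to (oh, ow), matching the floor/ceil window rule."""
    x = as_tensor(x)
    oh, ow = (out_hw, out_hw) if isinstance(out_hw, int) else out_hw
    n, c, h, w = x.shape
    hs = [(i * h // oh, -(-(i + 1) * h // oh)) for i in range(oh)]
    ws = [(j * w // ow, -(-(j + 1) * w // ow)) for j in range(ow)]
    out_data = np.empty((n, c, oh, ow))
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bwd(g):
        gx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += g[:, :, i, j, None, None] / area
        _acc(x, gx)

    return _make(out_data, (x,), bwd)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[i, i0c] += 1.0 - frac
        m[i, i1c] += frac
    return m


def upsample_bilinear(x, out_hw) -> Tensor:
    """Bilinear interpolation of an NCHW tensor to (oh, ow)."""
    x = as_tensor(x)
    oh, ow = (out_hw, out_hw) if isinstance(out_hw, int) else out_hw
    h, w = x.shape[-2], x.shape[-1]
    wh = _interp_matrix(h, oh)
    ww_t = _interp_matrix(w, ow).T
    out_data = np.matmul(np.matmul(wh, x.data), ww_t)

    def bwd(g):
        _acc(x, np.matmul(np.matmul(wh.T, g), ww_t.T))

    return _make(out_data, (x,), bwd)


# ---------------------------------------------------------------------
# token/grid reshape contract
# ---------------------------------------------------------------------

def tokens_to_grid(t: Tensor, h: int, w: int) -> Tensor:
    """(N, H*W, D) -> (N, D, H, W), row-major token order."""
    n, L, d = t.shape
    assert L == h * w, f"token count {L} != {h}x{w}"
    return transpose(reshape(t, (n, h, w, d)), (0, 3, 1, 2))


def grid_to_tokens(g: Tensor) -> Tensor:
    """(N, D, H, W) -> (N, H*W, D)."""
    n, d, h, w = g.shape
    return reshape(transpose(g, (0, 2, 3, 1)), (n, h * w, d))
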