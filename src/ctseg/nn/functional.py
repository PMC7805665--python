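"""Differentiable operations for 3D encoder-decoder segmentation networks.

All spatial tensors are laid out ``(batch, channels, D, H, W)``.  The
3x3x3 convolutions are evaluated as an im2col matrix product; the
strided down/up-sampling convolutions used by the fully convolutional
variant have kernel size equal to their stride, which reduces both the
forward and backward passes to a single einsum over non-overlapping
blocks.  Gradient formulas were verified against finite differences
(see the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, accumulate

__all__ = [
    "conv3d", "conv1x1", "down_conv", "up_conv", "max_pool",
    "upsample_linear", "concat", "add", "mul", "leaky_relu", "relu",
    "sigmoid", "instance_norm", "dropout", "softmax_channels",
    "linear_interp_matrix",
]


# ---------------------------------------------------------------------------
# dense 3D convolution (stride 1, odd kernel, "same" padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, ksize: tuple[int, int, int],
            pad: tuple[int, int, int]):
    """Patch matrix (B, C*k, P) built by per-offset slice copies.

    The batch-major layout keeps both the buffer fill and the following
    GEMM cache-friendly, which matters on a single CPU core.
    """
    nb, c = x.shape[:2]
    kd, kh, kw = ksize
    xp = np.pad(x, ((0, 0), (0, 0), (pad[0], pad[0]), (pad[1], pad[1]),
                    (pad[2], pad[2])))
    do = xp.shape[2] - kd + 1
    ho = xp.shape[3] - kh + 1
    wo = xp.shape[4] - kw + 1
    buf = np.empty((nb, c, kd * kh * kw, do, ho, wo), x.dtype)
    m = 0
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                buf[:, :, m] = xp[:, :, i:i + do, j:j + ho, l:l + wo]
                m += 1
    return buf.reshape(nb, c * kd * kh * kw, do * ho * wo), (do, ho, wo)


def _col_gemm(w2: np.ndarray, cols: np.ndarray, out_sp, out_ch: int):
    """(O, CK) x (B, CK, P) -> contiguous (B, O, *out_sp)."""
    nb = cols.shape[0]
    y = np.empty((nb, out_ch, cols.shape[2]), cols.dtype)
    for bi in range(nb):
        np.matmul(w2, cols[bi], out=y[bi])
    return y.reshape(nb, out_ch, *out_sp)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 "same" correlation; ``w`` has shape (O, C, kd, kh, kw)."""
    kd, kh, kw = w.data.shape[2:]
    pad = (kd // 2, kh // 2, kw // 2)
    nb = x.data.shape[0]
    o = w.data.shape[0]
    cols, out_sp = _im2col(x.data, (kd, kh, kw), pad)
    y = _col_gemm(w.data.reshape(o, -1), cols, out_sp, o)
    if b is not None:
        y += b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        dy_f = dy.reshape(nb, o, -1)
        if w.requires_grad:
            dw = np.zeros((o, cols.shape[1]), dy.dtype)
            for bi in range(nb):
                dw += dy_f[bi] @ cols[bi].T
            accumulate(w, dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            accumulate(b, dy.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            # gradient w.r.t. input is the "full" correlation with the
            # spatially flipped, channel-transposed kernel
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            fpad = (kd - 1 - pad[0], kh - 1 - pad[1], kw - 1 - pad[2])
            dcols, dsp = _im2col(dy, (kd, kh, kw), fpad)
            accumulate(x, _col_gemm(wt.reshape(wt.shape[0], -1), dcols,
                                    dsp, wt.shape[0]))

    return Tensor._result(y, parents, backward)


def conv1x1(x: Tensor, w: Tensor, b: Tensor | None = None,
            stride: tuple[int, int, int] = (1, 1, 1)) -> Tensor:
    """Channel-wise 1x1x1 convolution; ``w`` has shape (O, C).

    A stride > 1 subsamples the grid, which is how skip features are
    brought onto the coarser grid of the gating signal inside the
    attention gates.
    """
    sd, sh, sw = stride
    xs = x.data[:, :, ::sd, ::sh, ::sw]
    y = np.einsum("bcdhw,oc->bodhw", xs, w.data, optimize=True)
    if b is not None:
        y += b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        if w.requires_grad:
            accumulate(w, np.einsum("bodhw,bcdhw->oc", dy, xs, optimize=True))
        if b is not None and b.requires_grad:
            accumulate(b, dy.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dxs = np.einsum("bodhw,oc->bcdhw", dy, w.data, optimize=True)
            if stride == (1, 1, 1):
                accumulate(x, dxs)
            else:
                dx = np.zeros_like(x.data)
                dx[:, :, ::sd, ::sh, ::sw] = dxs
                accumulate(x, dx)

    return Tensor._result(y, parents, backward)


# ---------------------------------------------------------------------------
# block-strided convolutions (kernel == stride): down / up sampling
# ---------------------------------------------------------------------------

def _blocks(x: np.ndarray, f: tuple[int, int, int]) -> np.ndarray:
    """(B,C,D,H,W) -> (B,C,D/fd,fd,H/fh,fh,W/fw,fw) view."""
    b, c, d, h, w = x.shape
    return x.reshape(b, c, d // f[0], f[0], h // f[1], f[1], w // f[2], f[2])


def down_conv(x: Tensor, w: Tensor, b: Tensor | None,
              factors: tuple[int, int, int]) -> Tensor:
    """Strided convolution with kernel = stride = ``factors`` per axis.

    ``w`` has shape (O, C, fd, fh, fw).  Axes with factor 1 are left at
    full resolution, which realises per-axis downsampling budgets on
    anisotropic patches.
    """
    xb = _blocks(x.data, factors)
    y = np.einsum("bcdxhywz,ocxyz->bodhw", xb, w.data, optimize=True)
    if b is not None:
        y += b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        if w.requires_grad:
            accumulate(w, np.einsum("bodhw,bcdxhywz->ocxyz", dy, xb,
                                    optimize=True))
        if b is not None and b.requires_grad:
            accumulate(b, dy.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dxb = np.einsum("bodhw,ocxyz->bcdxhywz", dy, w.data,
                            optimize=True)
            accumulate(x, dxb.reshape(x.data.shape))

    return Tensor._result(y, parents, backward)


def up_conv(x: Tensor, w: Tensor, b: Tensor | None,
            factors: tuple[int, int, int]) -> Tensor:
    """Transposed convolution with kernel = stride = ``factors``.

    ``w`` has shape (C, O, fd, fh, fw); every input voxel paints one
    non-overlapping output block, the fully convolutional counterpart
    of interpolation upsampling.
    """
    nb, c, d, h, w_ = x.data.shape
    o = w.data.shape[1]
    yb = np.einsum("bcdhw,coxyz->bodxhywz", x.data, w.data, optimize=True)
    y = yb.reshape(nb, o, d * factors[0], h * factors[1], w_ * factors[2])
    if b is not None:
        y = y + b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(dy):
        dyb = _blocks(dy, factors).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        # dyb: (B,O,D,H,W,fd,fh,fw)
        if w.requires_grad:
            accumulate(w, np.einsum("bodhwxyz,bcdhw->coxyz", dyb, x.data,
                                    optimize=True))
        if b is not None and b.requires_grad:
            accumulate(b, dy.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            accumulate(x, np.einsum("bodhwxyz,coxyz->bcdhw", dyb, w.data,
                                    optimize=True))

    return Tensor._result(y, parents, backward)


def max_pool(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    """Max pooling over non-overlapping per-axis blocks."""
    nb, c, d, h, w = x.data.shape
    k = factors[0] * factors[1] * factors[2]
    xb = _blocks(x.data, factors).transpose(0, 1, 2, 4, 6, 3, 5, 7)
    out_sp = xb.shape[2:5]
    flat = np.ascontiguousarray(xb).reshape(nb, c, *out_sp, k)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(dy):
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dxb = dflat.reshape(nb, c, *out_sp, *factors).transpose(
            0, 1, 2, 5, 3, 6, 4, 7)
        accumulate(x, dxb.reshape(x.data.shape))

    return Tensor._result(y, (x,), backward)


# ---------------------------------------------------------------------------
# linear (trilinear in 3D) resizing
# ---------------------------------------------------------------------------

_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def linear_interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Sparse-in-spirit (n_out, n_in) linear interpolation matrix.

    Sampling positions follow the half-pixel convention: output index i
    reads the continuous input coordinate (i + 0.5) * n_in/n_out - 0.5,
    clamped at the edges.
    """
    key = (n_in, n_out)
    m = _INTERP_CACHE.get(key)
    if m is not None:
        return m
    m = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    _INTERP_CACHE[key] = m
    return m


def _apply_axis(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    y = np.tensordot(m.astype(x.dtype), x, axes=([1], [axis]))
    return np.moveaxis(y, 0, axis)


def upsample_linear(x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of the spatial axes of a (B,C,D,H,W) tensor."""
    mats = [linear_interp_matrix(x.data.shape[2 + a], out_spatial[a])
            for a in range(3)]
    y = x.data
    for a, m in enumerate(mats):
        if m.shape[0] != m.shape[1] or not np.array_equal(m, np.eye(m.shape[0])):
            y = _apply_axis(y, m, 2 + a)

    def backward(dy):
        if not x.requires_grad:
            return
        dx = dy
        for a, m in enumerate(mats):
            if m.shape[0] != m.shape[1] or not np.array_equal(m, np.eye(m.shape[0])):
                dx = _apply_axis(dx, m.T, 2 + a)
        accumulate(x, dx)

    return Tensor._result(y, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise / structural ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(dy):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * dy.ndim
                sl[axis] = slice(lo, hi)
                accumulate(t, dy[tuple(sl)])

    return Tensor._result(y, tuple(tensors), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    y = a.data + b.data

    def backward(dy):
        accumulate(a, dy)
        accumulate(b, dy)

    return Tensor._result(y, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise product with broadcasting (used for attention gating)."""
    y = a.data * b.data

    def _reduce(dg, shape):
        extra = dg.ndim - len(shape)
        if extra:
            dg = dg.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and dg.shape[i] > 1)
        if axes:
            dg = dg.sum(axis=axes, keepdims=True)
        return dg

    def backward(dy):
        if a.requires_grad:
            accumulate(a, _reduce(dy * b.data, a.data.shape))
        if b.requires_grad:
            accumulate(b, _reduce(dy * a.data, b.data.shape))

    return Tensor._result(y, (a, b), backward)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    y = np.where(x.data > 0, x.data, slope * x.data)

    def backward(dy):
        accumulate(x, np.where(x.data > 0, dy, slope * dy))

    return Tensor._result(y, (x,), backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def backward(dy):
        accumulate(x, np.where(x.data > 0, dy, 0))

    return Tensor._result(y, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def backward(dy):
        accumulate(x, dy * y * (1.0 - y))

    return Tensor._result(y, (x,), backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    axes = (2, 3, 4)
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xh = (x.data - mean) * inv
    g = gamma.data[None, :, None, None, None]
    y = g * xh + beta.data[None, :, None, None, None]

    def backward(dy):
        if gamma.requires_grad:
            accumulate(gamma, (dy * xh).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            accumulate(beta, dy.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dxh = dy * g
            m1 = dxh.mean(axis=axes, keepdims=True)
            m2 = (dxh * xh).mean(axis=axes, keepdims=True)
            accumulate(x, inv * (dxh - m1 - xh * m2))

    return Tensor._result(y, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype)
    scale = 1.0 / (1.0 - p)
    y = x.data * keep * scale

    def backward(dy):
        accumulate(x, dy * keep * scale)

    return Tensor._result(y, (x,), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis of a (B,C,...) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=1, keepdims=True)

    def backward(dy):
        if not x.requires_grad:
            return
        s = (dy * y).sum(axis=1, keepdims=True)
        accumulate(x, y * (dy - s))

    return Tensor._result(y, (x,), backward)
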