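"""Training objective: soft dice + cross-entropy on softmax outputs.

Both terms consume the per-voxel class probabilities ``u`` (softmax
output, a differentiable tensor) and a one-hot ground-truth encoding
``v`` (plain array).  The dice term is computed per class and per batch
sample, summed over classes with a -2/|C| weight, and averaged over the
batch; perfect one-hot agreement scores -1, disjoint supports score 0.
The cross-entropy term is averaged over voxels (rather than the printed
pure sum) so its magnitude is patch-size invariant; a pure-sum variant
is available via ``reduction='sum'``.
"""

from __future__ import annotations

import numpy as np

from .nn.tensor import Tensor

__all__ = ["one_hot", "dice_loss", "cross_entropy_loss", "total_loss",
           "DICE_EPS", "CE_CLAMP"]

DICE_EPS = 1e-5       # guards 0/0 for classes absent from u and v
CE_CLAMP = 1e-7       # lower clamp on probabilities inside the log


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(B, D, H, W) integer labels -> (B, C, D, H, W) one-hot float32."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("labels outside [0, num_classes)")
    v = np.zeros((labels.shape[0], num_classes) + labels.shape[1:],
                 np.float32)
    np.put_along_axis(v, labels[:, None].astype(np.int64), 1.0, axis=1)
    return v


def _check(u_data: np.ndarray, v: np.ndarray) -> None:
    if u_data.shape != v.shape:
        raise ValueError(f"shape mismatch: u {u_data.shape} vs v {v.shape}")
    if u_data.ndim < 3:
        raise ValueError("expected (B, C, spatial...) tensors")


def dice_loss(u: Tensor, v: np.ndarray,
              include_background: bool = True) -> Tensor:
    """Soft dice loss in [-1, 0]; see module docstring."""
    v = np.asarray(v, u.data.dtype)
    _check(u.data, v)
    b, c = u.data.shape[:2]
    sp = tuple(range(2, u.data.ndim))
    cls = slice(None) if include_background else slice(1, None)
    ud, vd = u.data[:, cls], v[:, cls]
    nc = ud.shape[1]
    num = (ud * vd).sum(axis=sp)                      # (B, C')
    den = ud.sum(axis=sp) + vd.sum(axis=sp) + DICE_EPS
    per_sample = (-2.0 / nc) * (num / den).sum(axis=1)
    value = per_sample.mean()

    def backward(dy):
        if not u.requires_grad:
            return
        # d/du of num/den, with num independent of u only through itself
        shape = (b, nc) + (1,) * len(sp)
        g = (vd * den.reshape(shape) - num.reshape(shape)) \
            / (den ** 2).reshape(shape)
        du = np.zeros_like(u.data)
        du[:, cls] = (-2.0 / (nc * b)) * g * dy
        from .nn.tensor import accumulate
        accumulate(u, du)

    return Tensor._result(np.asarray(value, u.data.dtype), (u,), backward)


def cross_entropy_loss(u: Tensor, v: np.ndarray,
                       reduction: str = "mean") -> Tensor:
    """Cross-entropy -sum_c v log(u) with probabilities clamped at 1e-7.

    ``reduction='mean'`` averages over batch and voxels;
    ``reduction='sum'`` keeps the raw double sum.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    v = np.asarray(v, u.data.dtype)
    _check(u.data, v)
    uc = np.clip(u.data, CE_CLAMP, 1.0)
    n_vox = u.data.shape[0] * int(np.prod(u.data.shape[2:]))
    total = -(v * np.log(uc)).sum()
    value = total / n_vox if reduction == "mean" else total

    def backward(dy):
        if not u.requires_grad:
            return
        du = np.where((u.data > CE_CLAMP) & (v > 0), -v / uc, 0.0)
        if reduction == "mean":
            du = du / n_vox
        from .nn.tensor import accumulate
        accumulate(u, du * dy)

    return Tensor._result(np.asarray(value, u.data.dtype), (u,), backward)


def total_loss(u: Tensor, v: np.ndarray, *,
               include_background: bool = True,
               ce_reduction: str = "mean") -> tuple[Tensor, float, float]:
    """Combined objective; returns (loss, dice_part, ce_part)."""
    from .nn import functional as F
    ld = dice_loss(u, v, include_background)
    lc = cross_entropy_loss(u, v, ce_reduction)
    return F.add(ld, lc), ld.item(), lc.item()
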