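"""Patch-wise prediction: half-overlap tiling, Gaussian importance
weighting, mirror test-time augmentation, full/low-resolution softmax
ensembling, and activation-map export.

Prediction accuracy degrades toward patch borders, so patches overlap
by half their size and per-voxel contributions are weighted by a
separable Gaussian centred on the patch (sigma = patch size / 8 per
axis, peak 1 at the centre).  The printed recipe sets boundary weights
to zero; here they are floored at a small epsilon so voxels covered
only by a patch border (volume corners) keep defined values.  With
test-time augmentation each patch is evaluated under all 8 mirror
reflections, predictions are un-mirrored and averaged in probability
space before weighting.

A "network" only needs a ``predict_proba(patch) -> (C, ...)`` method,
which keeps the stitching machinery testable with analytic stubs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import LabelMask, Volume

__all__ = ["WeightMap", "SoftmaxVolume", "gaussian_weights",
           "tile_positions", "predict_volume", "assemble", "argmax_mask",
           "export_activation_maps"]

WEIGHT_FLOOR = 1e-6


@dataclass
class WeightMap:
    weights: np.ndarray


@dataclass
class SoftmaxVolume:
    """C-channel probability grid sharing the input volume's geometry."""

    probs: np.ndarray                    # (C, D, H, W)
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None


def gaussian_weights(patch_size, floor: float = WEIGHT_FLOOR) -> WeightMap:
    """Separable Gaussian importance map, peak 1, sigma = size/8."""
    axes = []
    for n in patch_size:
        n = int(n)
        if n < 1:
            raise ValueError("patch size must be positive")
        c = (n - 1) / 2.0
        sigma = n / 8.0
        axes.append(np.exp(-((np.arange(n) - c) ** 2) / (2.0 * sigma ** 2)))
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    w /= w.max()
    return WeightMap(np.maximum(w, floor).astype(np.float64))


def tile_positions(volume_shape, patch_size) -> list[tuple[int, int, int]]:
    """Half-overlap tile corners covering the whole volume.

    Stride is half the patch per axis; the last tile is clamped so
    every voxel is covered.
    """
    per_axis = []
    for a in range(3):
        n, p = int(volume_shape[a]), int(patch_size[a])
        if n < p:
            raise ValueError(f"volume axis {a} smaller than the patch; "
                             "pad before tiling")
        stride = max(1, p // 2)
        starts = list(range(0, n - p + 1, stride))
        if starts[-1] != n - p:
            starts.append(n - p)
        per_axis.append(starts)
    return [tuple(c) for c in itertools.product(*per_axis)]


def _mirror_variants(tta: bool):
    if not tta:
        return [()]
    return [axes for r in range(4)
            for axes in itertools.combinations((0, 1, 2), r)]


def _pad_volume(data: np.ndarray, patch_size):
    pads = []
    for a in range(3):
        deficit = max(0, patch_size[a] - data.shape[a])
        pads.append((deficit // 2, deficit - deficit // 2))
    padded = np.pad(data, pads) if any(p != (0, 0) for p in pads) else data
    return padded, pads


def predict_volume(network, volume: Volume, patch_size,
                   tta: bool = True) -> SoftmaxVolume:
    """Stitched softmax prediction for one preprocessed volume."""
    patch_size = tuple(int(p) for p in patch_size)
    data, pads = _pad_volume(np.asarray(volume.data, np.float32), patch_size)
    w = gaussian_weights(patch_size).weights
    variants = _mirror_variants(tta)

    num = None
    den = np.zeros(data.shape, np.float64)
    for corner in tile_positions(data.shape, patch_size):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
        patch = data[sl]
        acc = None
        for axes in variants:
            view = np.flip(patch, axes) if axes else patch
            probs = np.asarray(network.predict_proba(view), np.float64)
            if probs.shape[1:] != patch.shape:
                raise ValueError(
                    f"network returned spatial shape {probs.shape[1:]} for "
                    f"patch {patch.shape}; check the plan/network pairing")
            if axes:
                probs = np.flip(probs, [a + 1 for a in axes])
            acc = probs if acc is None else acc + probs
        acc /= len(variants)
        if num is None:
            num = np.zeros((acc.shape[0],) + data.shape, np.float64)
        num[(slice(None),) + sl] += w * acc
        den[sl] += w
    probs = num / den
    crop = tuple(slice(p[0], data.shape[a] - p[1] or None)
                 for a, p in enumerate(pads))
    probs = probs[(slice(None),) + crop]
    return SoftmaxVolume(probs, volume.spacing, volume.affine)


def argmax_mask(sv: SoftmaxVolume, class_set=(0, 1, 2)) -> LabelMask:
    """Voxel-wise argmax; ties resolve to the lowest class index."""
    labels = np.argmax(sv.probs, axis=0).astype(np.int16)
    return LabelMask(labels, sv.spacing, sv.affine, class_set)


def assemble(full_res: SoftmaxVolume, low_res: SoftmaxVolume,
             class_set=(0, 1, 2)) -> LabelMask:
    """Average full- and low-resolution softmax maps, then argmax.

    The low-resolution probabilities are trilinearly resampled onto the
    full-resolution grid first and renormalized to the simplex.
    """
    target_shape = full_res.probs.shape[1:]
    lr = np.asarray(low_res.probs, np.float64)
    if lr.shape[1:] != target_shape:
        factors = [t / s for t, s in zip(target_shape, lr.shape[1:])]
        lr = np.stack([ndimage.zoom(lr[c], factors, order=1, mode="nearest")
                       for c in range(lr.shape[0])])
        if lr.shape[1:] != target_shape:
            raise ValueError("low-resolution map could not be resampled "
                             f"to {target_shape}")
        lr /= lr.sum(axis=0, keepdims=True)
    mean = 0.5 * (np.asarray(full_res.probs, np.float64) + lr)
    return argmax_mask(SoftmaxVolume(mean, full_res.spacing,
                                     full_res.affine), class_set)


def export_activation_maps(network, volume: Volume, patch_size,
                           out_dir=None):
    """Stitch attention-coefficient and secondary segmentation maps.

    Maps are accumulated tile-by-tile with the same Gaussian weighting
    as predictions and returned (and optionally written as NIfTI) on
    the input grid.  Networks without gates or supervision heads yield
    an empty export with a warning.
    """
    from .nn import functional as F

    patch_size = tuple(int(p) for p in patch_size)
    data, pads = _pad_volume(np.asarray(volume.data, np.float32), patch_size)
    w = gaussian_weights(patch_size).weights

    spec = network.spec
    if spec.ag_levels == 0 and spec.dsv_levels == 0:
        warnings.warn("network has neither attention gates nor deep "
                      "supervision; nothing to export", stacklevel=2)
        return {}

    sums: dict[str, np.ndarray] = {}
    den = np.zeros(data.shape, np.float64)
    for corner in tile_positions(data.shape, patch_size):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
        _, aux = network.forward(data[sl][None, None], mode="eval",
                                 capture=True)
        tile_maps: dict[str, np.ndarray] = {}
        for level, alpha in aux["attention"]:
            a = alpha[0, 0]
            if a.shape != patch_size:
                a = ndimage.zoom(a, [p / s for p, s in
                                     zip(patch_size, a.shape)], order=1)
            tile_maps[f"attention_level{level}"] = a
        for i, dsv in enumerate(aux["dsv"]):
            level = spec.dsv_levels - 1 - i
            m = dsv[0]
            for c in range(m.shape[0]):
                a = m[c]
                if a.shape != patch_size:
                    a = ndimage.zoom(a, [p / s for p, s in
                                         zip(patch_size, a.shape)], order=1)
                tile_maps[f"secondary_level{level}_class{c}"] = a
        for name, a in tile_maps.items():
            if name not in sums:
                sums[name] = np.zeros(data.shape, np.float64)
            sums[name][sl] += w * a
        den[sl] += w

    crop = tuple(slice(p[0], data.shape[a] - p[1] or None)
                 for a, p in enumerate(pads))
    maps = {name: (s / den)[crop] for name, s in sums.items()}
    if out_dir is not None:
        from .volume import write_volume
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, arr in maps.items():
            write_volume(Volume(arr.astype(np.float32), volume.spacing,
                                volume.affine), out_dir / f"{name}.nii.gz")
    return maps
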