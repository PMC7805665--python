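"""Dataset fingerprinting and intensity/geometry normalization.

The preprocessing contract, applied per dataset:

1. every case is resampled to the dataset's median voxel spacing
   (third-order spline for images, nearest neighbour for masks);
2. intensities are clipped to the [0.5, 99.5] percentiles of the values
   occurring inside the segmentation masks (any non-zero label), pooled
   over all cases;
3. z-score normalization with the pooled foreground mean and standard
   deviation.

For the low-resolution variant the target spacing is doubled until the
median resampled shape holds fewer than four times the voxels of one
input patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelMask, Volume

__all__ = ["DatasetFingerprint", "resample", "resample_volume",
           "resample_mask", "compute_fingerprint", "normalize",
           "lowres_spacing", "resampled_shape"]


@dataclass
class DatasetFingerprint:
    """Dataset-level statistics parameterizing preprocessing."""

    median_spacing: tuple[float, float, float]
    median_shape: tuple[int, int, int]
    fg_p005: float
    fg_p995: float
    fg_mean: float
    fg_std: float
    n_cases: int = 1

    def __post_init__(self):
        if self.fg_p005 > self.fg_p995:
            raise ValueError("percentiles out of order")
        if self.fg_std < 0:
            raise ValueError("negative standard deviation")
        if self.n_cases < 1:
            raise ValueError("fingerprint needs at least one case")

    def to_json(self, path) -> None:
        payload = {
            "median_spacing": list(self.median_spacing),
            "median_shape": list(self.median_shape),
            "fg_p005": self.fg_p005, "fg_p995": self.fg_p995,
            "fg_mean": self.fg_mean, "fg_std": self.fg_std,
            "n_cases": self.n_cases,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DatasetFingerprint":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["median_spacing"]), tuple(d["median_shape"]),
                   d["fg_p005"], d["fg_p995"], d["fg_mean"], d["fg_std"],
                   d.get("n_cases", 1))


def resampled_shape(shape, spacing, target_spacing) -> tuple[int, int, int]:
    """New grid shape per axis: round(old_shape * old / new spacing)."""
    return tuple(int(np.round(shape[a] * spacing[a] / target_spacing[a]))
                 for a in range(3))


def _zoom(data, factors, order):
    return ndimage.zoom(data, factors, order=order, mode="nearest",
                        grid_mode=False, prefilter=order > 1)


def resample_volume(vol: Volume, target_spacing) -> Volume:
    """Third-order spline resampling of image data."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if min(target_spacing) <= 0:
        raise ValueError("target spacing must be positive")
    new_shape = resampled_shape(vol.shape, vol.spacing, target_spacing)
    if new_shape == vol.shape and tuple(vol.spacing) == target_spacing:
        return Volume(vol.data.copy(), target_spacing, vol.affine)
    factors = [n / o for n, o in zip(new_shape, vol.shape)]
    data = _zoom(np.asarray(vol.data, np.float32), factors, order=3)
    assert data.shape == new_shape
    return Volume(data, target_spacing, vol.affine)


def resample_mask(mask: LabelMask, target_spacing) -> LabelMask:
    """Nearest-neighbour resampling; output values stay in the input set."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if min(target_spacing) <= 0:
        raise ValueError("target spacing must be positive")
    new_shape = resampled_shape(mask.shape, mask.spacing, target_spacing)
    factors = [n / o for n, o in zip(new_shape, mask.shape)]
    labels = _zoom(mask.labels, factors, order=0)
    assert labels.shape == new_shape
    return LabelMask(labels, target_spacing, mask.affine, mask.class_set)


def resample(volume_or_mask, target_spacing, mode: str):
    """Dispatch on ``mode``: 'image' (cubic spline) or 'mask' (nearest)."""
    if mode == "image":
        return resample_volume(volume_or_mask, target_spacing)
    if mode == "mask":
        return resample_mask(volume_or_mask, target_spacing)
    raise ValueError("mode must be 'image' or 'mask'")


def compute_fingerprint(cases) -> DatasetFingerprint:
    """Pool foreground statistics over (Volume, LabelMask) pairs.

    Foreground = every voxel with a non-zero label.  Median spacing and
    median post-resampling shape are medians of per-case values;
    percentiles use linear interpolation between order statistics.
    """
    spacings, shapes, fg_chunks = [], [], []
    for vol, mask in cases:
        if mask is None:
            raise ValueError("fingerprint requires labelled cases")
        if mask.shape != vol.shape:
            raise ValueError("image/mask shape mismatch")
        spacings.append(vol.spacing)
        shapes.append((vol.shape, vol.spacing))
        fg = np.asarray(vol.data)[np.asarray(mask.labels) > 0]
        if fg.size:
            fg_chunks.append(fg.astype(np.float64))
    if not fg_chunks:
        raise ValueError("dataset contains no foreground voxels")
    pooled = np.concatenate(fg_chunks)
    median_spacing = tuple(float(np.median([s[a] for s in spacings]))
                           for a in range(3))
    per_case_shapes = [resampled_shape(sh, sp, median_spacing)
                       for sh, sp in shapes]
    median_shape = tuple(int(np.round(np.median([s[a] for s in per_case_shapes])))
                         for a in range(3))
    p005, p995 = np.percentile(pooled, [0.5, 99.5])
    return DatasetFingerprint(
        median_spacing=median_spacing, median_shape=median_shape,
        fg_p005=float(p005), fg_p995=float(p995),
        fg_mean=float(pooled.mean()), fg_std=float(pooled.std()),
        n_cases=len(spacings))


def normalize(vol: Volume, fp: DatasetFingerprint) -> Volume:
    """Clip to the foreground percentile window, then z-score."""
    if fp.fg_std <= 0:
        raise ValueError("degenerate dataset: zero foreground variance")
    data = np.clip(np.asarray(vol.data, np.float32), fp.fg_p005, fp.fg_p995)
    data = (data - fp.fg_mean) / fp.fg_std
    return Volume(data.astype(np.float32), vol.spacing, vol.affine)


def lowres_spacing(fp: DatasetFingerprint, patch_size) -> tuple:
    """Median spacing doubled k times, k minimal such that the median
    shape holds fewer than 4x the voxels of one patch."""
    patch_voxels = int(np.prod([int(p) for p in patch_size]))
    if patch_voxels <= 0:
        raise ValueError("patch size must be positive")
    shape = np.asarray(fp.median_shape, np.float64)
    k = 0
    while np.prod(shape / 2 ** k) >= 4 * patch_voxels:
        k += 1
    return tuple(s * 2 ** k for s in fp.median_spacing)
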