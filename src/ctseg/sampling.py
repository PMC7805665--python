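"""Random patch extraction with a batch-level foreground guarantee, and
on-the-fly augmentation (rotation, scaling, elastic deformation, gamma
correction, mirroring).

Patches are cut on the fly from preprocessed cases.  A batch is only
useful for the imbalance-aware losses if it sees foreground at least
occasionally, so at least one patch per batch is forced to contain a
non-background voxel: the forced patch is centred on a uniformly chosen
foreground voxel (clipped to the volume bounds).  Volumes smaller than
the patch are symmetrically zero-padded (intensities are in normalized
z-score space, labels pad with background).

Spatial augmentations apply one composed coordinate map (affine
rotation+scaling plus an elastic displacement field) with cubic
interpolation for the image and nearest-neighbour for the labels, so
label values never leave the class set.  Gamma correction acts on the
image only; mirroring flips both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PatchPair", "AugmentConfig", "TrainingCase", "sample_patch",
           "sample_batch", "augment"]


@dataclass
class TrainingCase:
    """A preprocessed case held in memory for patch sampling."""

    case_id: str
    image: np.ndarray
    labels: np.ndarray
    _fg_coords: np.ndarray | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, np.float32)
        self.labels = np.asarray(self.labels)
        if self.image.shape != self.labels.shape:
            raise ValueError("image/label shape mismatch")

    @property
    def foreground_coords(self) -> np.ndarray:
        if self._fg_coords is None:
            self._fg_coords = np.argwhere(self.labels > 0)
        return self._fg_coords


@dataclass
class PatchPair:
    image: np.ndarray
    labels: np.ndarray
    case_id: str
    corner: tuple[int, int, int]

    def has_foreground(self) -> bool:
        return bool((self.labels > 0).any())


@dataclass
class AugmentConfig:
    """Defaults follow the conventions of on-the-fly medical-image
    augmentation pipelines; everything is overridable in the run
    config."""

    rotation_deg: float = 30.0
    p_rotation: float = 0.2
    scale_range: tuple[float, float] = (0.85, 1.25)
    p_scale: float = 0.2
    elastic_alpha: tuple[float, float] = (0.0, 200.0)
    elastic_sigma: tuple[float, float] = (9.0, 13.0)
    p_elastic: float = 0.2
    gamma_range: tuple[float, float] = (0.7, 1.5)
    p_gamma: float = 0.3
    p_mirror_per_axis: float = 0.5
    mirror_axes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        for lo, hi in (self.scale_range, self.elastic_alpha,
                       self.elastic_sigma, self.gamma_range):
            if lo > hi:
                raise ValueError("augmentation ranges must be (low, high)")
        for p in (self.p_rotation, self.p_scale, self.p_elastic,
                  self.p_gamma, self.p_mirror_per_axis):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _pad_to(arr: np.ndarray, patch_size, cval) -> np.ndarray:
    pads = []
    for a in range(3):
        deficit = max(0, patch_size[a] - arr.shape[a])
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, constant_values=cval)
    return arr


def sample_patch(case: TrainingCase, patch_size, rng: np.random.Generator,
                 force_foreground: bool = False) -> PatchPair:
    """Cut one patch; see module docstring for the sampling rules."""
    patch_size = tuple(int(p) for p in patch_size)
    image = _pad_to(case.image, patch_size, 0.0)
    labels = _pad_to(case.labels, patch_size, 0)
    shape = image.shape
    pad_off = [(shape[a] - case.image.shape[a]) // 2 for a in range(3)]

    if force_foreground:
        fg = case.foreground_coords
        if len(fg) == 0:
            warnings.warn(f"case {case.case_id} has no foreground; "
                          "sampling a random patch instead", stacklevel=2)
            force_foreground = False
    if force_foreground:
        voxel = fg[rng.integers(len(fg))]
        corner = [int(np.clip(voxel[a] + pad_off[a] - patch_size[a] // 2,
                              0, shape[a] - patch_size[a]))
                  for a in range(3)]
    else:
        corner = [int(rng.integers(0, shape[a] - patch_size[a] + 1))
                  for a in range(3)]
    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
    return PatchPair(image[sl].copy(), labels[sl].copy(), case.case_id,
                     tuple(corner))


def sample_batch(cases: list[TrainingCase], batch_size: int,
                 patch_size, rng: np.random.Generator) -> list[PatchPair]:
    """A batch of patches with at least one guaranteed-foreground member."""
    if not cases:
        raise ValueError("no cases to sample from")
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    forced = int(rng.integers(batch_size))
    batch = []
    for i in range(batch_size):
        case = cases[rng.integers(len(cases))]
        batch.append(sample_patch(case, patch_size, rng,
                                  force_foreground=(i == forced)))
    return batch


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def augment(pair: PatchPair, config: AugmentConfig,
            rng: np.random.Generator) -> PatchPair:
    """Augmented copy of a patch pair; shapes and class set unchanged."""
    image = pair.image
    labels = pair.labels
    shape = image.shape

    do_rot = rng.random() < config.p_rotation
    do_scale = rng.random() < config.p_scale
    do_elastic = rng.random() < config.p_elastic
    # draw parameters regardless, keeping the stream layout stable
    angles = np.deg2rad(rng.uniform(-config.rotation_deg,
                                    config.rotation_deg, 3))
    scale = rng.uniform(*config.scale_range)
    alpha = rng.uniform(*config.elastic_alpha)
    sigma = rng.uniform(*config.elastic_sigma)

    if do_rot or do_scale or do_elastic:
        mat = np.eye(3)
        if do_rot:
            mat = _rotation_matrix(angles)
        if do_scale:
            # sampling grid scaled by 1/s zooms the content by s
            mat = mat / scale
        center = (np.asarray(shape) - 1) / 2.0
        grid = np.indices(shape, dtype=np.float64)
        coords = np.einsum("ab,bxyz->axyz",
                           mat, grid - center.reshape(3, 1, 1, 1))
        coords += center.reshape(3, 1, 1, 1)
        if do_elastic:
            for a in range(3):
                noise = rng.uniform(-1, 1, shape)
                coords[a] += ndimage.gaussian_filter(noise, sigma) * alpha
        fill = float(image.min())
        image = ndimage.map_coordinates(image, coords, order=3,
                                        mode="constant", cval=fill)
        labels = ndimage.map_coordinates(labels, coords, order=0,
                                         mode="constant", cval=0)
        image = image.astype(np.float32)

    if rng.random() < config.p_gamma:
        gamma = rng.uniform(*config.gamma_range)
        lo, hi = float(image.min()), float(image.max())
        if hi > lo:
            unit = (image - lo) / (hi - lo)
            image = (unit ** gamma * (hi - lo) + lo).astype(np.float32)

    for axis in config.mirror_axes:
        if rng.random() < config.p_mirror_per_axis:
            image = np.flip(image, axis)
            labels = np.flip(labels, axis)

    return PatchPair(np.ascontiguousarray(image),
                     np.ascontiguousarray(labels),
                     pair.case_id, pair.corner)
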