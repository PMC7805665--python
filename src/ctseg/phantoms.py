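"""Synthetic abdominal-CT-like phantoms: one ellipsoidal organ with an
embedded spherical tumor on a noisy soft-tissue background.

The phantoms reproduce the statistical structure the segmentation
method is built around: a strong class imbalance (background ≫ organ >
tumor), a large smooth organ containing a small lesion, class intensity
distributions that overlap (adjacent class means are separated by about
one effective noise standard deviation), and optionally anisotropic
voxel spacing.  Every case is a deterministic function of its seed.

Default intensities are Hounsfield-like: background 40, organ 70,
tumor 100, per-class heterogeneity SD 10 and additive acquisition noise
SD 25, i.e. a separation of 30 ≈ 1.1 effective SDs -- learnable but not
trivial.  The organ occupies a few percent of the grid, so foreground
sampling and imbalance-aware losses actually matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import (LabelMask, Volume, write_manifest, write_mask,
                     write_volume)

__all__ = ["PhantomConfig", "generate_phantom", "generate_cases",
           "generate_dataset"]


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: organ semi-axes, as fractions of half the smallest physical extent
    organ_frac: tuple[float, float] = (0.35, 0.55)
    #: tumor radius as a fraction of the smallest organ semi-axis
    tumor_frac: tuple[float, float] = (0.35, 0.60)
    background_mean: float = 40.0
    organ_mean: float = 70.0
    tumor_mean: float = 100.0
    background_sd: float = 10.0
    organ_sd: float = 10.0
    tumor_sd: float = 10.0
    noise_sd: float = 25.0
    #: gaussian blur of the class-mean image, emulating partial volume
    smoothing_sigma: float = 1.0
    center_jitter: float = 0.10

    def __post_init__(self):
        if self.organ_frac[0] > self.organ_frac[1] \
                or self.tumor_frac[0] > self.tumor_frac[1]:
            raise ValueError("ranges must be (low, high)")
        if self.tumor_frac[1] >= 1.0:
            raise ValueError("tumor cannot fit: tumor_frac must stay "
                             "below the smallest organ semi-axis")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        for v in (self.background_sd, self.organ_sd, self.tumor_sd,
                  self.noise_sd):
            if not np.isfinite(v) or v < 0:
                raise ValueError("intensity SDs must be finite and >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_phantom(config: PhantomConfig,
                     rng: np.random.Generator) -> tuple[Volume, LabelMask]:
    """One organ+tumor case; all tumor voxels lie inside the organ."""
    shape = tuple(int(s) for s in config.shape)
    spacing = np.asarray(config.spacing, np.float64)
    extent = np.asarray(shape) * spacing
    half_min = extent.min() / 2.0

    semi = rng.uniform(*config.organ_frac, size=3) * half_min
    radius = rng.uniform(*config.tumor_frac) * semi.min()
    if radius >= semi.min():
        raise ValueError("infeasible geometry: tumor radius exceeds the "
                         "smallest organ semi-axis")
    rot = _random_rotation(rng)
    center = extent / 2.0 + rng.uniform(-config.center_jitter,
                                        config.center_jitter, 3) * extent

    # physical coordinates of voxel centres
    grids = np.meshgrid(*[(np.arange(shape[a]) + 0.5) * spacing[a]
                          for a in range(3)], indexing="ij")
    coords = np.stack([g - center[a] for a, g in enumerate(grids)])
    # organ frame: rotate, normalize by semi-axes
    local = np.einsum("ab,bxyz->axyz", rot, coords)
    organ = (local[0] / semi[0]) ** 2 + (local[1] / semi[1]) ** 2 \
        + (local[2] / semi[2]) ** 2 <= 1.0

    # tumor centre inside the eroded organ so the sphere fits entirely
    inner = semi - radius
    while True:
        offs = rng.uniform(-1.0, 1.0, 3) * inner
        if np.sum((offs / inner) ** 2) <= 1.0:
            break
    tumor_center = rot.T @ offs + center
    dist2 = sum((grids[a] - tumor_center[a]) ** 2 for a in range(3))
    tumor = (dist2 <= radius ** 2) & organ

    labels = np.zeros(shape, np.int16)
    labels[organ] = 1
    labels[tumor] = 2
    counts = np.bincount(labels.ravel(), minlength=3)
    if not (counts[0] > counts[1] > counts[2] > 0):
        raise ValueError(f"degenerate phantom: class counts {counts.tolist()}"
                         " do not satisfy background > organ > tumor > 0")

    means = np.array([config.background_mean, config.organ_mean,
                      config.tumor_mean], np.float32)[labels]
    if config.smoothing_sigma > 0:
        means = ndimage.gaussian_filter(means, config.smoothing_sigma)
    sds = np.array([config.background_sd, config.organ_sd,
                    config.tumor_sd], np.float32)[labels]
    data = means + rng.normal(0.0, 1.0, shape) * sds \
        + rng.normal(0.0, config.noise_sd, shape)
    vol = Volume(data.astype(np.float32), tuple(spacing))
    mask = LabelMask(labels, tuple(spacing))
    return vol, mask


def generate_cases(n: int, config: PhantomConfig,
                   seed: int) -> list[tuple[Volume, LabelMask]]:
    """n deterministic cases, each driven by a spawned child seed."""
    if n < 1:
        raise ValueError("need at least one case")
    children = np.random.SeedSequence(seed).spawn(n)
    return [generate_phantom(config, np.random.default_rng(c))
            for c in children]


def generate_dataset(n: int, config: PhantomConfig, out_dir,
                     seed: int = 0) -> Path:
    """Write n NIfTI case pairs plus a JSON manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (vol, mask) in enumerate(generate_cases(n, config, seed)):
        cid = f"phantom_{i:03d}"
        write_volume(vol, out_dir / f"{cid}_image.nii.gz")
        write_mask(mask, out_dir / f"{cid}_mask.nii.gz")
        entries.append({"id": cid, "image": f"{cid}_image.nii.gz",
                        "mask": f"{cid}_mask.nii.gz"})
    manifest = out_dir / "manifest.json"
    write_manifest(entries, manifest)
    return manifest
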