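"""Per-task training plans: resolution variant, patch geometry, per-axis
downsampling budgets and batch size.

The shipped presets are the published configurations for the three
abdominal organ/tumor tasks (kidney, liver, pancreas), each in a
full-resolution and a low-resolution variant.  Their median shapes are
stored verbatim as reported; the target spacing of a preset is the
median spacing of the user's copy of the dataset and is therefore left
unset here.  For custom datasets, plans are built from a fingerprint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import DatasetFingerprint, lowres_spacing

__all__ = ["Plan", "plan_for_task", "plan_from_fingerprint",
           "available_presets", "PRESETS"]


@dataclass
class Plan:
    task_name: str
    resolution: str                       # "full" | "low"
    patch_size: tuple[int, int, int]
    levels_per_axis: tuple[int, int, int]
    batch_size: int = 2
    target_spacing: tuple[float, float, float] | None = None
    median_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.patch_size = tuple(int(v) for v in self.patch_size)
        self.levels_per_axis = tuple(int(v) for v in self.levels_per_axis)
        if self.resolution not in ("full", "low"):
            raise ValueError("resolution must be 'full' or 'low'")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if max(self.levels_per_axis) > 5:
            raise ValueError("at most 5 downsamplings per axis")
        for a in range(3):
            if self.patch_size[a] % 2 ** self.levels_per_axis[a]:
                raise ValueError(
                    f"patch axis {a} ({self.patch_size[a]}) not divisible "
                    f"by 2^{self.levels_per_axis[a]}")
        bottleneck = min(self.patch_size[a] // 2 ** self.levels_per_axis[a]
                         for a in range(3))
        if bottleneck < 8:
            warnings.warn("bottleneck feature maps smaller than 8; this "
                          "matches several shipped presets but exceeds the "
                          "downsample-until-size-8 guideline", stacklevel=2)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "task_name": self.task_name, "resolution": self.resolution,
                "patch_size": list(self.patch_size),
                "levels_per_axis": list(self.levels_per_axis),
                "batch_size": self.batch_size,
                "target_spacing": (list(self.target_spacing)
                                   if self.target_spacing else None),
                "median_shape": (list(self.median_shape)
                                 if self.median_shape else None),
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Plan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["task_name"], d["resolution"], tuple(d["patch_size"]),
                   tuple(d["levels_per_axis"]), d.get("batch_size", 2),
                   tuple(d["target_spacing"]) if d.get("target_spacing")
                   else None,
                   tuple(d["median_shape"]) if d.get("median_shape")
                   else None)


#: published per-task configurations (patch, per-axis levels, batch,
#: reported median patient shape after resampling)
PRESETS: dict[tuple[str, str], dict] = {
    ("kidney", "full"): dict(patch=(160, 160, 48), levels=(5, 5, 3),
                             batch=2, median_shape=(511, 511, 136)),
    ("kidney", "low"): dict(patch=(128, 128, 80), levels=(5, 5, 4),
                            batch=2, median_shape=(247, 247, 127)),
    ("liver", "full"): dict(patch=(96, 128, 128), levels=(5, 5, 5),
                            batch=2, median_shape=(482, 512, 512)),
    ("liver", "low"): dict(patch=(96, 128, 128), levels=(5, 5, 5),
                           batch=2, median_shape=(189, 201, 201)),
    ("pancreas", "full"): dict(patch=(40, 192, 160), levels=(3, 5, 5),
                               batch=2, median_shape=(96, 512, 512)),
    ("pancreas", "low"): dict(patch=(64, 128, 128), levels=(3, 5, 5),
                              batch=2, median_shape=(88, 299, 299)),
}


def available_presets() -> list[str]:
    return sorted(f"{t}/{r}" for t, r in PRESETS)


def plan_for_task(task: str, resolution: str) -> Plan:
    """Return the shipped preset for (task, resolution)."""
    key = (str(task).lower(), str(resolution).lower())
    if key not in PRESETS:
        raise KeyError(
            f"no preset for {key[0]!r}/{key[1]!r}; available: "
            + ", ".join(available_presets()))
    p = PRESETS[key]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # presets knowingly go below size 8
        return Plan(task_name=key[0], resolution=key[1],
                    patch_size=p["patch"], levels_per_axis=p["levels"],
                    batch_size=p["batch"], median_shape=p["median_shape"])


def plan_from_fingerprint(fp: DatasetFingerprint, task_name: str,
                          resolution: str, patch_size,
                          levels_per_axis, batch_size: int = 2) -> Plan:
    """Build a plan for a user dataset.

    Full resolution targets the median spacing; the low-resolution
    variant doubles it (isotropically, factor 2 per halving step) until
    the median shape is below four patch volumes.
    """
    if resolution == "full":
        spacing = fp.median_spacing
        shape = fp.median_shape
    elif resolution == "low":
        spacing = lowres_spacing(fp, patch_size)
        ratio = spacing[0] / fp.median_spacing[0]
        shape = tuple(int(np.round(s / ratio)) for s in fp.median_shape)
    else:
        raise ValueError("resolution must be 'full' or 'low'")
    return Plan(task_name=task_name, resolution=resolution,
                patch_size=tuple(patch_size),
                levels_per_axis=tuple(levels_per_axis),
                batch_size=batch_size, target_spacing=spacing,
                median_shape=shape)
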