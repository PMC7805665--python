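"""Volumetric containers and NIfTI input/output.

A :class:`Volume` is a 3D scalar grid with per-axis voxel spacing (mm)
and the affine carried through unchanged from the source file; a
:class:`LabelMask` is its integer companion over an ordered class set
(0 = background).  Axis order follows the on-disk array; voxel indices
are 0-based.  Files are read and written with nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMask", "read_volume", "read_mask", "read_case",
           "write_volume", "write_mask", "read_manifest", "write_manifest"]


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """3D intensity grid + geometry (spacing in mm, affine carried)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must have exactly 3 axes")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError("spacing must be three positive values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, np.float64)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMask:
    """Integer label grid sharing a Volume's geometry."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    class_set: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMask must have exactly 3 axes")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, np.float64)
        present = set(np.unique(self.labels).tolist())
        allowed = set(int(c) for c in self.class_set)
        if not present <= allowed:
            raise ValueError(f"labels {sorted(present - allowed)} outside "
                             f"class set {sorted(allowed)}")

    @property
    def shape(self):
        return self.labels.shape


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, np.asarray(img.affine))


def read_mask(path, class_set=(0, 1, 2)) -> LabelMask:
    img = nib.load(str(path))
    labels = np.rint(np.asarray(img.dataobj)).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(labels, spacing, np.asarray(img.affine), class_set)


def read_case(image_path, mask_path=None, class_set=(0, 1, 2)):
    """Load an image and (optionally) its mask; shapes must agree."""
    vol = read_volume(image_path)
    if mask_path is None:
        return vol, None
    mask = read_mask(mask_path, class_set)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image "
                         f"shape {vol.shape}")
    return vol, mask


def _save(arr, affine, spacing, path):
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_volume(vol: Volume, path) -> None:
    _save(np.asarray(vol.data, np.float32), vol.affine, vol.spacing, path)


def write_mask(mask: LabelMask, path) -> None:
    _save(np.asarray(mask.labels, np.int16), mask.affine, mask.spacing, path)


# ---------------------------------------------------------------------------
# dataset manifest: case id -> image/mask paths (relative to the manifest)
# ---------------------------------------------------------------------------

def write_manifest(cases: list[dict], path) -> None:
    path = Path(path)
    path.write_text(json.dumps({"cases": cases}, indent=2))


def read_manifest(path) -> list[dict]:
    path = Path(path)
    payload = json.loads(path.read_text())
    cases = payload["cases"]
    out = []
    for c in cases:
        entry = dict(c)
        entry["image"] = str((path.parent / c["image"]).resolve())
        if c.get("mask"):
            entry["mask"] = str((path.parent / c["mask"]).resolve())
        out.append(entry)
    return out
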