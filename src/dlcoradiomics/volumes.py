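"""Image and mask containers plus NRRD / NIfTI round-trip I/O.

A volume is a 3-D scalar grid in Hounsfield units with physical voxel
spacing and origin.  Array axes are ``(x, y, z)``; ``spacing_mm`` follows
the same axis order, so ``spacing_mm[2]`` is the slice thickness.  Physical
position of voxel ``(i, j, k)`` is ``origin_mm + (i, j, k) * spacing_mm``.
Masks are binary grids aligned voxel-for-voxel with their image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
]


@dataclass(frozen=True)
class ImageVolume:
    """3-D scalar grid (HU) with physical geometry."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxels must be finite")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Same geometry, new voxel grid."""
        return ImageVolume(voxels, self.spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class MaskVolume:
    """Binary grid aligned to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={v.ndim}")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask voxels must be in {0, 1}")
        object.__setattr__(self, "voxels", v.astype(bool))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, other) -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")


# ---------------------------------------------------------------------------
# I/O.  SimpleITK indexes images (x, y, z) but hands numpy arrays (z, y, x);
# the transposes below keep our (x, y, z) array convention.

def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image):
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NRRD or NIfTI-1 (chosen from the file suffix)."""
    path = Path(path)
    try:
        sitk.WriteImage(_to_sitk(volume.voxels, volume.spacing_mm, volume.origin_mm), str(path))
    except RuntimeError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing {path}: {exc}") from exc
    return path


def write_mask(mask: MaskVolume, path: str | Path) -> Path:
    """Write a mask as unsigned 8-bit {0, 1}."""
    path = Path(path)
    try:
        sitk.WriteImage(
            _to_sitk(mask.voxels.astype(np.uint8), mask.spacing_mm, mask.origin_mm), str(path)
        )
    except RuntimeError as exc:  # pragma: no cover
        raise OSError(f"failed writing {path}: {exc}") from exc
    return path


def read_volume(path: str | Path) -> ImageVolume:
    try:
        voxels, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    except RuntimeError as exc:
        raise OSError(f"failed reading {path}: {exc}") from exc
    return ImageVolume(voxels.astype(np.float64), spacing, origin)


def read_mask(path: str | Path) -> MaskVolume:
    try:
        voxels, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    except RuntimeError as exc:
        raise OSError(f"failed reading {path}: {exc}") from exc
    return MaskVolume(voxels != 0, spacing, origin)
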