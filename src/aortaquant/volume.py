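"""3D scalar volumes with physical spacing — the raster currency of the pipeline.

Array axes are (x, y, z) in nibabel's RAS-ish convention; a voxel index maps to
physical coordinates as ``world_mm = index * spacing_mm + origin_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import InputError

__all__ = ["Volume", "Mask", "resample_isotropic"]


@dataclass
class Volume:
    """A 3D scalar image (HU) with physical spacing and origin in mm."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise InputError("volume must be 3D")
        if not np.all(self.spacing_mm > 0):
            raise InputError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis."""
        return np.asarray(self.shape) * self.spacing_mm

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing_mm + self.origin_mm

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.spacing_mm

    def save_nifti(self, path: str | Path) -> None:
        affine = np.diag(np.append(self.spacing_mm, 1.0))
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), affine), str(path))

    @classmethod
    def load_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        return cls(np.asarray(img.dataobj, dtype=np.float32), spacing, affine[:3, 3])


@dataclass
class Mask(Volume):
    """Binary raster sharing the Volume physical conventions."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = np.asarray(self.voxels).astype(bool)

    def save_nifti(self, path: str | Path) -> None:
        affine = np.diag(np.append(self.spacing_mm, 1.0))
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), str(path))

    @classmethod
    def load_nifti(cls, path: str | Path) -> "Mask":
        v = Volume.load_nifti(path)
        return cls(v.voxels > 0.5, v.spacing_mm, v.origin_mm)


def resample_isotropic(v: Volume, target_mm: float, order: int = 1) -> Volume:
    """Resample a volume to isotropic spacing by linear interpolation.

    The physical extent is preserved to within one output voxel; the origin is
    kept at the same world position.
    """
    if target_mm <= 0:
        raise InputError("target spacing must be positive")
    if not np.all(np.isfinite(v.voxels)):
        raise InputError("volume contains non-finite voxels")
    zoom = v.spacing_mm / float(target_mm)
    out = ndimage.zoom(np.asarray(v.voxels, dtype=np.float32), zoom, order=order,
                       mode="nearest", grid_mode=True)
    return Volume(out, np.full(3, float(target_mm)), v.origin_mm.copy())


def resample_mask_isotropic(m: Mask, target_mm: float) -> Mask:
    """Resample a binary mask (linear on the indicator, threshold at 0.5)."""
    v = resample_isotropic(Volume(m.voxels.astype(np.float32), m.spacing_mm, m.origin_mm),
                           target_mm)
    return Mask(v.voxels >= 0.5, v.spacing_mm, v.origin_mm)
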