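"""Voxel volumes: binary surface/mask grids and HU attenuation images.

Volumes are carried as a plain grid plus physical metadata (spacing in
mm/voxel, origin in mm).  NIfTI is the on-disk format, via nibabel; the
affine is assumed axis-aligned (diagonal spacing plus translation), which
holds for the segmentation products this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "VoxelVolume",
    "read_volume",
    "write_volume",
    "voxel_to_pointcloud",
    "emphysema_score",
    "lumen_volume",
]

KINDS = ("surface_labels", "hu_attenuation", "lung_mask", "lumen_mask")
BINARY_KINDS = ("surface_labels", "lung_mask", "lumen_mask")


@dataclass
class VoxelVolume:
    grid: np.ndarray
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "surface_labels"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be positive componentwise")
        if self.kind in BINARY_KINDS:
            vals = np.unique(self.grid)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{self.kind} volume must be binary")


def read_volume(path: str | Path, kind: str) -> VoxelVolume:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    if kind in BINARY_KINDS:
        grid = (grid > 0).astype(np.uint8)
    else:
        grid = np.rint(grid).astype(np.int16)
    return VoxelVolume(grid, spacing, origin, kind, [f"read nifti {path}"])


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    dtype = np.uint8 if vol.kind in BINARY_KINDS else np.int16
    nib.save(nib.Nifti1Image(vol.grid.astype(dtype), aff), str(path))


def voxel_to_pointcloud(vol: VoxelVolume) -> np.ndarray:
    """One 3D point (mm) per voxel with value 1: origin + index * spacing."""
    if vol.kind not in BINARY_KINDS:
        raise ValueError("voxel_to_pointcloud requires a binary volume")
    idx = np.argwhere(vol.grid == 1)
    if len(idx) == 0:
        raise DegenerateInputError("volume contains no 1-voxels")
    return idx * np.asarray(vol.spacing) + np.asarray(vol.origin)


def emphysema_score(
    hu: VoxelVolume, lung_mask: VoxelVolume, threshold_hu: int = -950
) -> float:
    """Percentage of lung voxels with attenuation below ``threshold_hu``.

    The conventional low-attenuation-area score (LAA%); computed over the
    whole masked volume, not slice-wise.
    """
    if hu.grid.shape != lung_mask.grid.shape:
        raise ValueError("HU volume and lung mask grids are not aligned")
    mask = lung_mask.grid == 1
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty lung mask")
    low = int(np.sum(hu.grid[mask] < threshold_hu))
    return 100.0 * low / n


def lumen_volume(lumen_mask: VoxelVolume) -> int:
    """Number of voxels inside the airway lumen (physical volume is this
    count times the voxel volume)."""
    if lumen_mask.kind not in BINARY_KINDS:
        raise ValueError("lumen_volume requires a binary mask")
    return int(np.sum(lumen_mask.grid == 1))
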