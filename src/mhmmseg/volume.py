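"""Spacing-aware 3-D volume containers and file I/O.

Volumes are stored as ``(nx, ny, nz)`` arrays indexed ``[i, j, k]`` with an
anisotropic voxel spacing in millimetres and a world-space origin, so that the
world coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``.
Axes are axis-aligned (no direction cosines); this is sufficient for the
synthetic phantoms and resampled clinical grids the package targets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3-D scalar or label volume with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional index coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers, one 1-D array per axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def like(self, data: np.ndarray) -> "Volume":
        """A new volume on the same grid holding ``data``."""
        return Volume(data, self.spacing, self.origin)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write to NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) with spacing."""
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asanyarray(volume.data), affine), path)
    elif path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.T))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported volume format: {path}")


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI or MetaImage volume (axis-aligned grids only)."""
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return Volume(np.asanyarray(img.dataobj), spacing, origin)
    if path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        return Volume(
            sitk.GetArrayFromImage(img).T.copy(),
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
        )
    raise ValueError(f"unsupported volume format: {path}")
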