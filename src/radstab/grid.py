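"""Volume and ROI data model.

A :class:`VolumeGrid` is a 3D scalar field of CT numbers (Hounsfield units)
on a regular lattice with physical voxel spacing; a :class:`ROIMask` is a
binary voxel set on the same lattice.  Array axes are ordered ``(z, y, x)``
with ``spacing`` in mm per voxel along the same axes; the ``(y, x)`` plane is
the axial (in-plane) section.  Voxel coordinates are 0-based index triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGrid",
    "ROIMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
]


@dataclass
class VolumeGrid:
    """3D scalar volume (HU) with voxel spacing in mm.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Scalar intensity per voxel, in HU.
    spacing : tuple of 3 floats
        Physical size of a voxel (mm) along (z, y, x).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """Binary voxel set on a :class:`VolumeGrid` lattice.

    ``data`` is a boolean array of the same shape as the host volume; member
    voxels are the True entries.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of member voxels |Omega|."""
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """Member voxels as an (n, 3) array of (z, y, x) index triples."""
        return np.argwhere(self.data)

    def check_compatible(self, volume: VolumeGrid) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def _spacing_to_sitk(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    # SimpleITK spacing order is (x, y, z); ours is (z, y, x).
    return (spacing[2], spacing[1], spacing[0])


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    img = sitk.GetImageFromArray(volume.values)
    img.SetSpacing(_spacing_to_sitk(volume.spacing))
    sitk.WriteImage(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    """Read a volume from NIfTI or MetaImage."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(float)
    sx, sy, sz = img.GetSpacing()
    return VolumeGrid(arr, (sz, sy, sx))


def save_mask(mask: ROIMask, path: str | Path) -> None:
    """Write a mask as a 0/1 volume on the same grid."""
    img = sitk.GetImageFromArray(mask.data.astype(np.uint8))
    img.SetSpacing(_spacing_to_sitk(mask.spacing))
    sitk.WriteImage(img, str(path))


def load_mask(path: str | Path) -> ROIMask:
    """Read a 0/1 mask volume."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img) > 0
    sx, sy, sz = img.GetSpacing()
    return ROIMask(arr, (sz, sy, sx))
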