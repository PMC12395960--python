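"""Scalar and label volumes with voxel spacing, plus NIfTI round-trip I/O.

Arrays are indexed ``(x, y, z)`` with ``z`` the craniocaudal axis, matching
the nibabel data-array convention for RAS-aligned images.  Spacing is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_volume", "write_volume"]


@dataclass
class Volume:
    """A 3-D scalar grid (HU, density, or integer labels) with geometry.

    Parameters
    ----------
    data:
        3-D array.  Float for HU / density volumes, integer for label masks.
    spacing:
        Voxel edge lengths in mm, one per axis ``(x, y, z)``.
    origin:
        World coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def is_label(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer) or self.data.dtype == bool

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.origin, dict(self.meta))


def _affine(vol: Volume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving spacing and origin in the affine."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(vol))
    if np.issubdtype(data.dtype, np.integer):
        img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def read_volume(path: str | Path, label: bool = False) -> Volume:
    """Read a NIfTI volume; with ``label=True`` the data are cast to int32."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if label:
        data = np.rint(data).astype(np.int32)
    else:
        data = np.asarray(data, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data, tuple(float(z) for z in zooms), origin)
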