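"""Scalar volume container and NIfTI I/O.

All stages of the pipeline operate on 3-D scalar grids with isotropic
spacing.  World coordinates are ``index * spacing + origin`` (a diagonal
affine); the same convention is used everywhere, including mesh vertices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["ScalarVolume", "read_volume", "write_volume"]


@dataclass
class ScalarVolume:
    """A 3-D scalar field on an isotropic voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing : float
        Isotropic voxel size in mm.
    origin : ndarray, shape (3,)
        World coordinate (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing
        aff[:3, 3] = self.origin
        return aff

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """A new volume on the same grid with different values."""
        return replace(self, data=np.asarray(data))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def world_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) for every voxel."""
        nx, ny, nz = self.shape
        x = np.arange(nx)[:, None, None] * self.spacing + self.origin[0]
        y = np.arange(ny)[None, :, None] * self.spacing + self.origin[1]
        z = np.arange(nz)[None, None, :] * self.spacing + self.origin[2]
        return x, y, z


def read_volume(path) -> ScalarVolume:
    """Load a 3-D NIfTI file as a :class:`ScalarVolume`.

    The grid must have (near-)isotropic spacing; anisotropic input raises a
    warning and uses the mean zoom.  4-D input is rejected.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        warnings.warn(
            f"{path}: anisotropic voxels {zooms}; using mean spacing", stacklevel=2
        )
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return ScalarVolume(np.asarray(data, dtype=np.float32), float(zooms.mean()), origin)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms((vol.spacing,) * 3)
    nib.save(img, str(path))
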