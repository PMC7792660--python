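"""Volumetric image carriers and NIfTI-1 I/O.

The pipeline works on 3D T2w-like intensity volumes and binary masks with
anisotropic voxels (the default phantom grid is 1 x 1 x 2 mm, mirroring an
axial T2w acquisition with 1 mm in-plane resolution and 2 mm slices).
Header voxel dimensions are authoritative; grid coordinates are 0-based
voxel indices and every physical quantity downstream is in mm / mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "BinaryMask", "read_volume", "read_mask", "write_volume", "write_mask"]


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel dimensions in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity grid, arbitrary units.
    voxel_size : tuple of float
        (dx, dy, dz) in mm, all strictly positive.
    orientation : str
        Axis-label record mapping grid axes to anatomical axes
        (RAS-style code, e.g. ``"RAS"``). Informational only.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if min(self.data.shape) < 1:
            raise ValueError("every grid axis must have length >= 1")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel dimensions must be three positive numbers, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.voxel_size, self.orientation)


@dataclass
class BinaryMask:
    """A 3D boolean grid annotating a :class:`Volume3D` of the same geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D data")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel dimensions must be three positive numbers, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def check_alignment(self, other) -> None:
        """Raise if *other* (Volume3D or BinaryMask) has a different geometry."""
        if self.shape != other.shape:
            raise ValueError(f"misaligned shapes: {self.shape} vs {other.shape}")
        if not np.allclose(self.voxel_size, other.voxel_size):
            raise ValueError(f"voxel sizes differ: {self.voxel_size} vs {other.voxel_size}")


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI-1 file into a :class:`Volume3D`.

    Voxel dimensions are taken from the header (``pixdim``); intensities are
    returned unmodified. A missing file, a non-3D image or non-positive
    voxel dimensions each raise a distinct error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel dimensions {zooms} in {path}")
    try:
        orientation = "".join(nib.aff2axcodes(img.affine))
    except Exception:
        orientation = "RAS"
    return Volume3D(np.asarray(data, dtype=np.float64), zooms, orientation)


def read_mask(path) -> BinaryMask:
    """Read a 3D NIfTI-1 file as a binary mask (non-zero voxels are True)."""
    vol = read_volume(path)
    return BinaryMask(vol.data != 0, vol.voxel_size)


def write_volume(vol: Volume3D, path) -> None:
    """Write a :class:`Volume3D` as NIfTI-1 with a diagonal affine."""
    data = np.asarray(vol.data)
    if data.dtype not in (np.float32, np.float64, np.int16, np.int32, np.uint8, np.uint16):
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine_from_voxel_size(vol.voxel_size))
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8),
                          _affine_from_voxel_size(mask.voxel_size))
    img.header.set_zooms(mask.voxel_size)
    nib.save(img, str(path))
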