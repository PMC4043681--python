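"""Calibrated-density and binary volume containers plus standard-format I/O.

Volumes are 3D scalar grids of mineral density in mgHA/cm^3 on an isotropic
grid. Index order is (slice, row, column) with axis 0 the anatomical long
axis. Voxel size is carried in micrometres.

Supported on-disk formats: NIfTI (.nii/.nii.gz, via nibabel), multi-page
TIFF (.tif/.tiff, via tifffile, ImageJ-style spacing metadata) and
MHD+RAW (.mhd, via SimpleITK). Anisotropic voxels are rejected on read:
every downstream measurement assumes an isotropic grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["DensityVolume", "BinaryVolume", "read_volume", "write_volume"]

_ISO_RTOL = 1e-4  # relative tolerance when checking voxel isotropy on read


@dataclass
class DensityVolume:
    """3D grid of calibrated mineral density (mgHA/cm^3).

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Density values. Finite; may be negative after noise addition.
    voxel_size : float
        Isotropic voxel edge length in micrometres.
    """

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with all dims >= 1")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return (self.voxel_size / 1000.0) ** 3

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.values.copy(), self.voxel_size)


@dataclass
class BinaryVolume:
    """Segmented bone mask on the same grid as its source DensityVolume."""

    mask: np.ndarray
    voxel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D boolean array")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size / 1000.0) ** 3

    def bone_voxel_count(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(self.mask.copy(), self.voxel_size, dict(self.provenance))


def _check_isotropic(zooms, path) -> float:
    zooms = np.asarray(zooms, dtype=float)
    if np.any(zooms <= 0):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    if np.ptp(zooms) > _ISO_RTOL * zooms.mean():
        raise ValueError(
            f"{path}: anisotropic voxels {tuple(zooms)} are not supported; "
            "the analysis assumes an isotropic grid"
        )
    return float(zooms.mean())


def write_volume(vol: DensityVolume, path: str | os.PathLike) -> None:
    """Write a DensityVolume with voxel size recorded in the file metadata."""
    path = os.fspath(path)
    lower = path.lower()
    data = vol.values.astype(np.float32)
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        mm = vol.voxel_size / 1000.0
        affine = np.diag([mm, mm, mm, 1.0])
        # nibabel is (x, y, z)-ordered on disk; transpose so axis 0 round-trips
        img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
        img.header.set_zooms((mm, mm, mm))
        nib.save(img, path)
    elif lower.endswith((".tif", ".tiff")):
        import tifffile

        um = vol.voxel_size
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / um, 1.0 / um),
            metadata={"spacing": um, "unit": "um"},
        )
    elif lower.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(data)
        mm = vol.voxel_size / 1000.0
        img.SetSpacing((mm, mm, mm))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unrecognized volume format: {path}")


def read_volume(path: str | os.PathLike, voxel_size: Optional[float] = None) -> DensityVolume:
    """Read a density volume; ``voxel_size`` (um) overrides/supplies metadata.

    Raises if the format is unknown, the voxels are anisotropic, or no voxel
    size is recorded and no override is given.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64).T
        um = _check_isotropic(img.header.get_zooms()[:3], path) * 1000.0
        if voxel_size is not None:
            um = float(voxel_size)
        return DensityVolume(data, um)
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(np.float64)
            um = None
            meta = tif.imagej_metadata or {}
            page = tif.pages[0]
            if "spacing" in meta and page.tags.get("XResolution") is not None:
                xres = page.tags["XResolution"].value
                xy = xres[1] / xres[0]  # um per pixel when written by write_volume
                um = _check_isotropic([meta["spacing"], xy, xy], path)
        if voxel_size is not None:
            um = float(voxel_size)
        if um is None:
            raise ValueError(
                f"{path}: no voxel-size metadata found; pass voxel_size= explicitly"
            )
        if data.ndim == 2:
            data = data[None]
        return DensityVolume(data, um)
    if lower.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img).astype(np.float64)
        um = _check_isotropic(img.GetSpacing(), path) * 1000.0
        if voxel_size is not None:
            um = float(voxel_size)
        return DensityVolume(data, um)
    raise ValueError(f"unrecognized volume format: {path}")
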