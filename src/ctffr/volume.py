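"""3-D scalar CT volumes and their file formats.

A :class:`CTVolume` is a scalar grid with physical metadata: voxel
spacing in millimetres and a world-space origin.  Intensities are
HU-like arbitrary units (contrast-enhanced lumen bright, soft tissue
dark).  MetaImage (.mhd/.raw) and DICOM series go through SimpleITK,
NIfTI through nibabel; the array axis order is (z, y, x) with
``spacing`` stored as (dz, dy, dx) mm to match.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["CTVolume", "read_volume", "write_volume", "read_dicom_series"]


@dataclass
class CTVolume:
    """Scalar volume with voxel spacing (mm) and origin (mm).

    ``data`` is indexed ``[z, y, x]``; ``spacing`` and ``origin`` follow
    the same axis order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def physical_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write to .mhd/.mha (MetaImage) or .nii/.nii.gz (NIfTI) by extension."""
    path = os.fspath(path)
    if path.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
        # SimpleITK metadata is (x, y, z)
        img.SetSpacing(tuple(vol.spacing[::-1]))
        img.SetOrigin(tuple(vol.origin[::-1]))
        sitk.WriteImage(img, path)
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing[::-1]) + [1.0])
        affine[:3, 3] = vol.origin[::-1]
        # NIfTI is Fortran-ordered (x, y, z): transpose from (z, y, x)
        nib.save(nib.Nifti1Image(np.asarray(vol.data.T), affine), path)
    else:
        raise ValidationError(f"unsupported volume format: {path}")


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a MetaImage or NIfTI volume written by :func:`write_volume`."""
    path = os.fspath(path)
    if path.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        return CTVolume(
            data=sitk.GetArrayFromImage(img),
            spacing=tuple(img.GetSpacing()[::-1]),
            origin=tuple(img.GetOrigin()[::-1]),
        )
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        origin = img.affine[:3, 3]
        return CTVolume(
            data=np.asanyarray(img.dataobj).T,
            spacing=tuple(float(z) for z in zooms[::-1]),
            origin=tuple(float(o) for o in origin[::-1]),
        )
    raise ValidationError(f"unsupported volume format: {path}")


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Load a DICOM series from a directory, slices ordered by image position."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(os.fspath(directory))
    if not files:
        raise ValidationError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    return CTVolume(
        data=sitk.GetArrayFromImage(img),
        spacing=tuple(img.GetSpacing()[::-1]),
        origin=tuple(img.GetOrigin()[::-1]),
    )
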