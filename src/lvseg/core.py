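"""Core volumetric containers and file I/O.

A :class:`Volume` is a 3D scalar image with anisotropic voxel spacing; a
:class:`LabelMask` is its binary counterpart.  Arrays are indexed ``[x, y, z]``
so that axis ``i`` of the array corresponds to component ``i`` of ``spacing``
and ``origin``; the world coordinate of voxel index ``v`` (voxel center,
0-based) is ``origin + v * spacing``.

Volumes round-trip through MetaImage (``.mhd`` + ``.raw``) via SimpleITK and
through NIfTI (``.nii`` / ``.nii.gz``) via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["Volume", "LabelMask", "read_volume", "read_mask", "write_volume", "write_mask"]


@dataclass
class Volume:
    """3D scalar image with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of fractional voxel indices, shape (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LabelMask(Volume):
    """Binary 3D mask sharing geometry with its paired :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)

    def matches(self, vol: Volume) -> bool:
        return self.shape == vol.shape and np.allclose(self.spacing, vol.spacing)

    def foreground_volume_ml(self) -> float:
        """Foreground volume in millilitres (voxel count x voxel volume / 1000)."""
        return float(self.data.sum()) * self.voxel_volume() / 1000.0


def _to_sitk(vol: Volume) -> sitk.Image:
    # SimpleITK arrays are (z, y, x); ours are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write as MetaImage (``.mhd``) or NIfTI (``.nii``/``.nii.gz``) by extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.diag([*vol.spacing, 1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))
    elif name.endswith(".mhd"):
        sitk.WriteImage(_to_sitk(vol), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume(data, tuple(float(z) for z in zooms), origin)
    if name.endswith(".mhd"):
        data, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
        return Volume(data, spacing, origin)
    raise ValueError(f"unsupported volume format: {path.suffix}")


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    return write_volume(Volume(mask.data.astype(np.uint8), mask.spacing, mask.origin), path)


def read_mask(path: str | Path) -> LabelMask:
    vol = read_volume(path)
    return LabelMask((np.asarray(vol.data) > 0.5).astype(np.uint8), vol.spacing, vol.origin)
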