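"""Volumetric containers and image I/O.

A :class:`VoxelVolume` is a 3D scalar grid in Hounsfield Units; a
:class:`NoduleMask` is a congruent binary grid marking one delineation of
the lesion.  Arrays are indexed ``(x, y, z)`` with 0-based voxel indices;
the conversion to/from the itk ``(z, y, x)`` memory order happens at the
I/O boundary and nowhere else.

Supported on-disk formats are NRRD (default) and NIfTI, dispatched on the
file extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

_IMAGE_EXTENSIONS = (".nrrd", ".nii", ".nii.gz")


@dataclass
class VoxelVolume:
    """A 3D CT signal around one nodule, in Hounsfield Units."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class NoduleMask:
    """One rater's (or the consensus) binary delineation of a nodule."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


def check_congruent(vol: VoxelVolume | NoduleMask, *others: VoxelVolume | NoduleMask) -> None:
    """Raise if shapes or spacings differ between the volume and any mask."""
    for other in others:
        if other.shape != vol.shape:
            raise ValueError(f"shape mismatch: {other.shape} vs {vol.shape}")
        if not np.allclose(other.spacing, vol.spacing):
            raise ValueError(f"spacing mismatch: {other.spacing} vs {vol.spacing}")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _IMAGE_EXTENSIONS):
        raise ValueError(
            f"unrecognised image format {path.name!r}; expected one of {_IMAGE_EXTENSIONS}"
        )


def write_image(obj: VoxelVolume | NoduleMask, path: str | Path) -> None:
    path = Path(path)
    _check_extension(path)
    if isinstance(obj, NoduleMask):
        arr = obj.values.astype(np.uint8)
    else:
        arr = obj.values.astype(np.float64)
    # numpy (x, y, z) -> itk (z, y, x) memory order
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(obj.spacing)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelVolume(values=arr.astype(np.float64), spacing=tuple(img.GetSpacing()))


def read_mask(path: str | Path) -> NoduleMask:
    """Read a binary mask; values other than {0, 1} are rejected."""
    path = Path(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask {path} is not binary: values {uniq[:10]}")
    return NoduleMask(values=arr.astype(bool), spacing=tuple(img.GetSpacing()))
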