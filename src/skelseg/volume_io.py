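"""Reading and writing CT volumes and binary masks.

All in-memory arrays follow one axis convention across the package:
``voxels[slice, row, col]`` with the slice (axial) index on axis 0 and, within
a slice, rows running top to bottom and columns left to right.  The stretcher
geometry assumes the couch faces the LEFT image edge; the ``orientation``
flag applied at load time lets callers bring arbitrarily exported data into
that frame.

NIfTI (.nii/.nii.gz) is the on-disk format for volumes and masks; a DICOM
series directory is accepted read-only, with the rescale slope/intercept
applied so voxels are always in Hounsfield units.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from .errors import (
    FileMissingError,
    NonNumericDataError,
    NotThreeDimensionalError,
    VolumeFormatError,
    VolumeWriteError,
)

__all__ = [
    "CTVolume",
    "MaskVolume",
    "MaskRole",
    "Orientation",
    "load_volume",
    "load_mask",
    "save_volume",
]

ORIENTATIONS = ("as-is", "rotate90", "rotate180", "rotate270", "flip-lr")


class Orientation(str, enum.Enum):
    """In-plane reorientation applied at load so the stretcher faces the left edge."""

    AS_IS = "as-is"
    ROTATE90 = "rotate90"
    ROTATE180 = "rotate180"
    ROTATE270 = "rotate270"
    FLIP_LR = "flip-lr"


class MaskRole(str, enum.Enum):
    SKELETON = "skeleton"
    STRETCHER = "stretcher"
    BACKGROUND_COMPLEMENT = "background-complement"


def _validate_grid(voxels: np.ndarray, spacing) -> None:
    if voxels.ndim != 3:
        raise NotThreeDimensionalError(
            f"expected a 3D (slice, row, col) array, got {voxels.ndim} axes"
        )
    if not np.issubdtype(voxels.dtype, np.number):
        raise NonNumericDataError(f"non-numeric voxel dtype {voxels.dtype!r}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing!r}")


@dataclass
class CTVolume:
    """A 3D CT grid in Hounsfield units.

    Parameters
    ----------
    voxels:
        3D array indexed ``[slice, row, col]``; values in HU, finite.
    spacing:
        Voxel size ``(dz, dy, dx)`` in millimetres.
    patient_id:
        Free-form identifier carried through the pipeline.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (2.5, 0.9766, 0.9766)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _validate_grid(self.voxels, self.spacing)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def slice_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return replace(self, voxels=voxels)

    def copy(self) -> "CTVolume":
        return replace(self, voxels=self.voxels.copy())


@dataclass
class MaskVolume:
    """A binary mask on the same grid as its parent :class:`CTVolume`."""

    voxels: np.ndarray
    role: MaskRole = MaskRole.SKELETON
    spacing: tuple[float, float, float] = (2.5, 0.9766, 0.9766)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _validate_grid(self.voxels, self.spacing)
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]!r}")
        self.voxels = self.voxels.astype(np.uint8)
        self.role = MaskRole(self.role)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def slice_count(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "MaskVolume":
        return replace(self, voxels=self.voxels.copy())


def _apply_orientation(voxels: np.ndarray, orientation: str | Orientation) -> np.ndarray:
    orientation = Orientation(orientation)
    if orientation is Orientation.AS_IS:
        return voxels
    if orientation is Orientation.FLIP_LR:
        return voxels[:, :, ::-1].copy()
    k = {Orientation.ROTATE90: 1, Orientation.ROTATE180: 2, Orientation.ROTATE270: 3}[orientation]
    return np.ascontiguousarray(np.rot90(voxels, k=k, axes=(1, 2)))


def _load_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated classes
        raise VolumeFormatError(f"cannot parse {path!r} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.dtype.names is not None or not np.issubdtype(data.dtype, np.number):
        raise NonNumericDataError(f"{path!r} carries non-numeric payload {data.dtype!r}")
    if data.ndim != 3:
        raise NotThreeDimensionalError(f"{path!r} has {data.ndim} axes, expected 3")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    # NIfTI stores (col, row, slice); transpose to (slice, row, col).
    voxels = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return voxels, spacing


def _load_dicom_series(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    if not files:
        raise VolumeFormatError(f"DICOM directory {path!r} is empty")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise VolumeFormatError(f"cannot parse {f!r} as DICOM: {exc}") from exc
        slices.append(ds)

    def _z(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=_z)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(slope * arr + intercept)
    voxels = np.stack(planes, axis=0)
    if voxels.ndim != 3:
        raise NotThreeDimensionalError("DICOM series did not stack to a 3D volume")
    first = slices[0]
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0]))
    if len(slices) > 1:
        dz = abs(_z(slices[1]) - _z(slices[0])) or float(
            getattr(first, "SliceThickness", 1.0) or 1.0
        )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    return voxels, (dz, dy, dx)


def load_volume(
    path: str | os.PathLike,
    orientation: str | Orientation = Orientation.AS_IS,
    patient_id: str | None = None,
) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Voxels are returned in Hounsfield units (DICOM rescale slope/intercept
    applied) with axis order ``(slice, row, col)``; ``orientation`` is applied
    in-plane so the stretcher-facing edge becomes the left image edge.

    Raises
    ------
    FileMissingError, VolumeFormatError, NotThreeDimensionalError,
    NonNumericDataError
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileMissingError(f"no such file or directory: {path!r}")
    if os.path.isdir(path):
        voxels, spacing = _load_dicom_series(path)
    else:
        voxels, spacing = _load_nifti(path)
    voxels = _apply_orientation(voxels, orientation)
    if patient_id is None:
        base = os.path.basename(path.rstrip("/"))
        patient_id = base.split(".nii")[0]
    return CTVolume(voxels=voxels, spacing=spacing, patient_id=patient_id)


def load_mask(
    path: str | os.PathLike,
    role: MaskRole | str = MaskRole.SKELETON,
    orientation: str | Orientation = Orientation.AS_IS,
    patient_id: str | None = None,
) -> MaskVolume:
    """Load a binary mask; values must be exactly {0, 1} after rounding."""
    vol = load_volume(path, orientation=orientation, patient_id=patient_id)
    voxels = np.rint(vol.voxels).astype(np.int64)
    return MaskVolume(
        voxels=voxels, role=MaskRole(role), spacing=vol.spacing, patient_id=vol.patient_id
    )


def save_volume(volume: CTVolume | MaskVolume, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI.

    Masks are written as uint8; HU volumes as int16 when all values are
    integral and in range, else float32.  ``load_volume(path)`` round-trips
    integer payloads bit-exactly.
    """
    path = os.fspath(path)
    voxels = volume.voxels
    if isinstance(volume, MaskVolume):
        data = voxels.astype(np.uint8)
    else:
        is_integral = np.issubdtype(voxels.dtype, np.integer) or np.all(
            voxels == np.rint(voxels)
        )
        if is_integral and voxels.min() >= -(2**15) and voxels.max() < 2**15:
            data = voxels.astype(np.int16)
        else:
            data = voxels.astype(np.float32)
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, path)
    except Exception as exc:
        raise VolumeWriteError(f"cannot write {path!r}: {exc}") from exc
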