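"""Grid-aware 3D volume and mask containers with world-coordinate semantics.

A :class:`VolumeGrid` couples a 3D data lattice with voxel spacing (mm), a
world-space origin, and an orthonormal direction matrix, so that every
downstream quantity denominated in physical units (contour volumes in cc,
Hausdorff distances in mm) is spacing-aware. Voxel indices are 0-based and
world coordinates follow ``world = origin + direction @ (index * spacing)``.

NIfTI is the canonical on-disk format; DICOM series import is read-only.
Masks travel as NIfTI volumes with values {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Optional, Sequence

import nibabel as nib
import numpy as np
import pydicom
import SimpleITK as sitk

from .errors import GridMismatchError, VolumeFormatError

# Header round-off tolerances for declaring two grids "the same".
GRID_ATOL_MM = 1e-4
DIRECTION_ATOL = 1e-6

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "ScanRecord",
    "read_volume",
    "read_mask",
    "write_volume",
    "assert_same_grid",
    "mask_volume_cc",
    "GRID_ATOL_MM",
    "DIRECTION_ATOL",
]


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with physical-space geometry.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Voxel values. ``NaN`` marks undefined voxels in derived maps.
    spacing : sequence of 3 floats
        Per-axis voxel size in mm; strictly positive.
    origin : sequence of 3 floats
        World position (mm) of voxel ``(0, 0, 0)``.
    direction : (3, 3) ndarray
        Orthonormal matrix whose columns are the world directions of the
        three index axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal within 1e-6")

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index-to-world affine (mm)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (self.direction @ (idx * np.asarray(self.spacing)).T).T + np.asarray(
            self.origin
        )

    def same_grid_as(
        self,
        other: "VolumeGrid",
        atol_mm: float = GRID_ATOL_MM,
        atol_dir: float = DIRECTION_ATOL,
    ) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol_mm)
            and np.allclose(self.origin, other.origin, atol=atol_mm)
            and np.allclose(self.direction, other.direction, atol=atol_dir)
        )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume on this grid carrying different voxel values."""
        return VolumeGrid(data, self.spacing, self.origin, self.direction.copy())

    # -- SimpleITK bridge --------------------------------------------------

    def to_sitk(self, dtype=None) -> sitk.Image:
        arr = self.data if dtype is None else self.data.astype(dtype)
        # SimpleITK arrays are indexed [z, y, x]; our axis 0 becomes ITK x.
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeGrid":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            arr,
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
            np.asarray(img.GetDirection()).reshape(3, 3),
        )


class BinaryMask(VolumeGrid):
    """A :class:`VolumeGrid` restricted to boolean values (a contour/ROI)."""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:5]}")
            data = data.astype(bool)
        self.data = data
        super().__post_init__()

    @property
    def volume_cc(self) -> float:
        """Mask volume in cm^3: voxel count x voxel volume / 1000."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_mm3 / 1000.0

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data, self.spacing, self.origin, self.direction.copy())


@dataclass
class ScanRecord:
    """One timepoint's bundle of co-registered volumes on a shared grid.

    ``quality`` is the binary map of voxels whose spectra passed quality
    filtering; ``contour`` is the metabolic-abnormality mask; ``nawm`` the
    contralateral normal-appearing-white-matter reference ROI. Either a
    precomputed ``ratio`` map or both ``cho`` and ``naa`` must be present
    before contouring is requested.
    """

    anatomy: VolumeGrid
    quality: BinaryMask
    cho: Optional[VolumeGrid] = None
    naa: Optional[VolumeGrid] = None
    ratio: Optional[VolumeGrid] = None
    linewidth: Optional[VolumeGrid] = None
    contour: Optional[BinaryMask] = None
    nawm: Optional[BinaryMask] = None
    timepoint_label: str = "other"

    def __post_init__(self) -> None:
        if self.timepoint_label not in ("pre_RT", "mid_RT", "other"):
            raise ValueError(f"unknown timepoint label {self.timepoint_label!r}")
        assert_same_grid(list(self.volumes()))

    def volumes(self) -> Iterator[VolumeGrid]:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, VolumeGrid):
                yield v

    def members(self) -> Iterator[tuple[str, VolumeGrid]]:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, VolumeGrid):
                yield f.name, v

    def has_ratio_source(self) -> bool:
        return self.ratio is not None or (self.cho is not None and self.naa is not None)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _detect_format(path) -> str:
    p = Path(path)
    if p.is_dir():
        return "dicom_series"
    if p.suffixes and p.suffixes[-1] in (".nii", ".gz"):
        return "nifti"
    return "nifti"


def read_volume(path, format: Optional[str] = None) -> VolumeGrid:
    """Read a 3D volume from NIfTI or a DICOM series directory.

    The returned grid carries spacing/origin/direction from the file header;
    voxel data are unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {fmt!r}")


def read_mask(path, format: Optional[str] = None) -> BinaryMask:
    """Read a binary mask; values must be {0, 1} after rounding tolerance."""
    vol = read_volume(path, format)
    data = vol.data
    if not np.all(np.isin(np.unique(data), (0, 1))):
        raise VolumeFormatError(f"{path}: mask file contains values outside {{0,1}}")
    return BinaryMask(data.astype(bool), vol.spacing, vol.origin, vol.direction)


def _read_nifti(path: Path) -> VolumeGrid:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeFormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing in header")
    direction = lin / spacing
    return VolumeGrid(data, tuple(spacing), tuple(aff[:3, 3]), direction)


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume (or mask, as uint8) to NIfTI."""
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def _read_dicom_series(directory: Path) -> VolumeGrid:
    files = sorted(
        p for p in directory.iterdir() if p.is_file() and not p.name.startswith(".")
    )
    if not files:
        raise VolumeFormatError(f"{directory}: empty DICOM series directory")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise VolumeFormatError(f"{f}: unreadable DICOM file ({exc})") from exc
        slices.append((f, ds))

    iop = np.asarray(slices[0][1].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[3:6], iop[0:3]  # world dirs of increasing row / column
    normal = np.cross(col_dir, row_dir)
    normal /= np.linalg.norm(normal)

    def slice_pos(ds):
        return float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))

    slices.sort(key=lambda fs: slice_pos(fs[1]))
    positions = np.array([slice_pos(ds) for _, ds in slices])
    if len(slices) < 2:
        slice_spacing = float(getattr(slices[0][1], "SliceThickness", 1.0))
    else:
        gaps = np.diff(positions)
        slice_spacing = float(np.median(gaps))
        bad = np.where(np.abs(gaps - slice_spacing) > 1e-3 * max(slice_spacing, 1.0))[0]
        if bad.size:
            i = int(bad[0])
            raise VolumeFormatError(
                f"inconsistent slice spacing in series {directory}: gap of "
                f"{gaps[i]:.4f} mm before slice {slices[i + 1][0].name} "
                f"(expected {slice_spacing:.4f} mm)"
            )
    pixel_spacing = [float(v) for v in slices[0][1].PixelSpacing]  # (row, col)
    arrays = [ds.pixel_array for _, ds in slices]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise VolumeFormatError(f"{directory}: slices differ in pixel dimensions")
    data = np.stack(arrays, axis=-1)  # (rows, cols, nslices)
    direction = np.column_stack([row_dir, col_dir, normal])
    origin = tuple(np.asarray(slices[0][1].ImagePositionPatient, dtype=float))
    return VolumeGrid(data, (pixel_spacing[0], pixel_spacing[1], slice_spacing),
                      origin, direction)


# ---------------------------------------------------------------------------
# Grid checks and derived quantities
# ---------------------------------------------------------------------------


def assert_same_grid(
    volumes: Sequence[VolumeGrid],
    atol_mm: float = GRID_ATOL_MM,
    atol_dir: float = DIRECTION_ATOL,
) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    if not volumes:
        raise ValueError("assert_same_grid requires a nonempty list")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if v.shape != ref.shape:
            raise GridMismatchError(
                f"volume {i}: shape {v.shape} != reference {ref.shape}"
            )
        if not np.allclose(v.spacing, ref.spacing, atol=atol_mm):
            raise GridMismatchError(
                f"volume {i}: spacing {v.spacing} != reference {ref.spacing}"
            )
        if not np.allclose(v.origin, ref.origin, atol=atol_mm):
            raise GridMismatchError(
                f"volume {i}: origin {v.origin} != reference {ref.origin}"
            )
        if not np.allclose(v.direction, ref.direction, atol=atol_dir):
            raise GridMismatchError(f"volume {i}: direction matrix differs")


def mask_volume_cc(mask: BinaryMask) -> float:
    """Mask volume in cc (cm^3): voxel count x voxel volume / 1000."""
    return mask.volume_cc
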