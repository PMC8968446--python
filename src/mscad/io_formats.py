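"""Volume I/O: NIfTI-1 files, DICOM series, and annotated DICOM output.

The universal in-memory carrier is :class:`VolumeImage`, a 3-D scalar grid
with physical geometry.  All inputs are reoriented to the closest RAS axis
convention on load so that downstream subtraction operates on co-indexed
grids.  Voxel indices are 0-based and the physical position of index
``(i, j, k)`` is ``origin + direction @ (spacing * (i, j, k))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import (
    ExplicitVRLittleEndian,
    MRImageStorage,
    SecondaryCaptureImageStorage,
    generate_uid,
)

from .errors import AmbiguousSeriesError, FormatError, GeometryError

if TYPE_CHECKING:  # pragma: no cover
    import SimpleITK as sitk

    from .report import LesionReport

__all__ = [
    "Geometry",
    "VolumeImage",
    "read_volume",
    "write_volume",
    "export_overlay_dicom",
]

_ORTHO_ATOL = 1e-6

# RAS <-> LPS flip for DICOM, whose patient coordinates are LPS.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


@dataclass(frozen=True)
class Geometry:
    """Physical geometry of a 3-D grid: spacing (mm), origin (mm), direction."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    direction: tuple[float, ...]  # row-major 3x3

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = self.direction_matrix * np.asarray(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_physical(self, index) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = idx * np.asarray(self.spacing) @ self.direction_matrix.T
        pts = pts + np.asarray(self.origin)
        return pts[0] if np.asarray(index).ndim == 1 else pts

    def physical_to_index(self, point) -> np.ndarray:
        pt = np.atleast_2d(np.asarray(point, dtype=float)) - np.asarray(self.origin)
        idx = (pt @ self.direction_matrix) / np.asarray(self.spacing)
        return idx[0] if np.asarray(point).ndim == 1 else idx


def _check_direction(direction: np.ndarray) -> None:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise GeometryError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d.T @ d, np.eye(3), atol=_ORTHO_ATOL):
        raise GeometryError("direction matrix is not orthonormal within 1e-6")


@dataclass
class VolumeImage:
    """A 3-D scalar image with physical geometry.

    Parameters
    ----------
    voxels
        3-D array indexed ``[i, j, k]``; arbitrary MR intensity units.
    spacing
        Per-axis voxel size in mm; all components > 0.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    direction
        3x3 orthonormal matrix whose columns are the physical directions of
        the three index axes.
    meta
        Free-form string metadata (patient/session/series identifiers).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise GeometryError(
                f"voxel grid must be 3-D with all dims >= 1, got {self.voxels.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.origin.shape != (3,):
            raise GeometryError("origin must be a 3-vector")
        _check_direction(self.direction)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def geometry(self) -> Geometry:
        return Geometry(
            spacing=tuple(float(s) for s in self.spacing),
            origin=tuple(float(o) for o in self.origin),
            direction=tuple(float(d) for d in self.direction.ravel()),
        )

    @property
    def affine(self) -> np.ndarray:
        return self.geometry.affine

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        return self.geometry.index_to_physical(index)

    def physical_to_index(self, point) -> np.ndarray:
        return self.geometry.physical_to_index(point)

    def same_grid(self, other: "VolumeImage", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """Same geometry and metadata, new voxel data."""
        return VolumeImage(
            voxels=voxels,
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            direction=self.direction.copy(),
            meta=dict(self.meta),
        )

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> "sitk.Image":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.voxels.transpose(2, 1, 0).astype(np.float64))
        )
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        img.SetDirection(tuple(float(d) for d in self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: "sitk.Image", meta: dict | None = None) -> "VolumeImage":
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            voxels=arr,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
            meta=dict(meta or {}),
        )


# ---------------------------------------------------------------------------
# reorientation
# ---------------------------------------------------------------------------

def _reorient_to_ras(arr: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute/flip axes so the affine is as close to RAS-aligned as possible."""
    ornt = nib.orientations.io_orientation(affine)
    arr2 = nib.orientations.apply_orientation(arr, ornt)
    aff2 = affine @ nib.orientations.inv_ornt_aff(ornt, arr.shape)
    return arr2, aff2


def _volume_from_affine(arr: np.ndarray, affine: np.ndarray, meta: dict) -> VolumeImage:
    arr, affine = _reorient_to_ras(arr, affine)
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("degenerate affine: zero-length axis")
    direction = m / spacing
    # Tolerate mild float drift in stored headers, reject truly sheared grids.
    u, _, vt = np.linalg.svd(direction)
    ortho = u @ vt
    if not np.allclose(ortho, direction, atol=1e-3):
        raise GeometryError("non-orthogonal voxel axes (sheared grid) are unsupported")
    return VolumeImage(
        voxels=arr, spacing=spacing, origin=affine[:3, 3], direction=ortho, meta=meta
    )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> VolumeImage:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad files
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    arr = np.asarray(img.dataobj).astype(np.float32)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {arr.shape}")
    meta = {"source": str(path)}
    descr = img.header.get("descrip")
    if descr is not None:
        meta["description"] = np.asarray(descr).tobytes().split(b"\x00")[0].decode(
            "latin-1", "ignore"
        )
    return _volume_from_affine(arr, img.affine, meta)


def write_volume(v: VolumeImage, path) -> None:
    """Write ``v`` as a NIfTI-1 file (float32) whose geometry round-trips."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(np.asarray(v.voxels, dtype=np.float32), v.affine)
    img.header.set_qform(v.affine, code=1)
    img.header.set_sform(v.affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _read_dicom_series(directory: Path) -> VolumeImage:
    datasets = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except (InvalidDicomError, Exception):
            continue
    datasets = [ds for ds in datasets if hasattr(ds, "PixelData")]
    if not datasets:
        raise FormatError(f"no readable DICOM image files in {directory}")

    series = {ds.get("SeriesInstanceUID", "unknown") for ds in datasets}
    if len(series) > 1:
        raise AmbiguousSeriesError(
            f"{directory} contains {len(series)} DICOM series; expected exactly one"
        )

    ref = datasets[0]
    iop = np.asarray([float(x) for x in ref.ImageOrientationPatient], dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]  # along increasing column / row index
    normal = np.cross(row_dir, col_dir)
    for ds in datasets:
        if not np.allclose(
            [float(x) for x in ds.ImageOrientationPatient], iop, atol=1e-4
        ):
            raise GeometryError("inconsistent ImageOrientationPatient across slices")

    datasets.sort(key=lambda ds: float(np.dot(normal, [float(x) for x in ds.ImagePositionPatient])))
    positions = np.asarray(
        [[float(x) for x in ds.ImagePositionPatient] for ds in datasets]
    )
    if len(datasets) > 1:
        steps = np.dot(positions[1:] - positions[:-1], normal)
        mean_step = float(np.mean(steps))
        if mean_step <= 0:
            raise GeometryError("non-increasing slice positions")
        if np.max(np.abs(steps - mean_step)) > 0.01 * abs(mean_step):
            raise GeometryError(
                "inter-slice spacing varies by more than 1% across the series"
            )
        slice_spacing = mean_step
    else:
        slice_spacing = float(
            ref.get("SpacingBetweenSlices", ref.get("SliceThickness", 1.0))
        )

    pix_spacing = [float(x) for x in ref.PixelSpacing]  # (row, col)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices, axis=0)  # (slice, row, col)
    voxels = stack.transpose(2, 1, 0)  # (col=i, row=j, slice=k)

    direction_lps = np.stack([row_dir, col_dir, normal], axis=1)
    direction = _LPS_TO_RAS @ direction_lps
    origin = _LPS_TO_RAS @ positions[0]
    spacing = np.asarray([pix_spacing[1], pix_spacing[0], slice_spacing])

    meta = {"source": str(directory)}
    for tag in ("PatientID", "PatientName", "StudyInstanceUID", "SeriesInstanceUID",
                "SeriesDescription", "StudyDate"):
        if tag in ref:
            meta[tag] = str(ref.get(tag))

    affine = np.eye(4)
    affine[:3, :3] = direction * spacing
    affine[:3, 3] = origin
    return _volume_from_affine(voxels, affine, meta)


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 file or a directory holding exactly one DICOM series.

    Volumes are reoriented to the closest RAS axis order; DICOM rescale
    slope/intercept is always applied.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return _read_nifti(path)


# ---------------------------------------------------------------------------
# Secondary-capture overlay export
# ---------------------------------------------------------------------------

def _base_sc_dataset(meta: dict, series_uid: str, instance: int) -> FileDataset:
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=file_meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.ImageType = ["DERIVED", "SECONDARY"]
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = meta.get("StudyInstanceUID", generate_uid())
    ds.SeriesDescription = "CAD lesion overlay"
    ds.PatientID = meta.get("PatientID", "UNKNOWN")
    ds.PatientName = meta.get("PatientName", "UNKNOWN")
    ds.InstanceNumber = instance
    ds.ConversionType = "WSD"
    return ds


def _to_uint8(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.clip((arr - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)


def export_overlay_dicom(tp1: VolumeImage, tp2: VolumeImage, report: "LesionReport",
                         out_dir) -> None:
    """Write one secondary-capture DICOM per axial slice.

    Each frame is a composite: Timepoint-1, Timepoint-2 and annotated
    Timepoint-2 side by side (new lesions red, false positives green), with
    an unannotated 2x-enlarged Timepoint-2 below.
    """
    if not tp1.same_grid(tp2):
        raise GeometryError("overlay export requires tp1 and tp2 on the same grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    nx, ny, nz = tp1.shape
    lo = float(min(tp1.voxels.min(), tp2.voxels.min()))
    hi = float(max(tp1.voxels.max(), tp2.voxels.max()))

    new_mask = np.zeros(tp1.shape, dtype=bool)
    fp_mask = np.zeros(tp1.shape, dtype=bool)
    for cand in getattr(report, "candidates", []):
        idx = np.asarray(cand.voxel_indices)
        target = new_mask if cand.is_new_lesion else fp_mask
        target[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    series_uid = generate_uid()
    hp, wp = ny, nx  # panel height/width: rows=j, cols=i
    for k in range(nz):
        p1 = _to_uint8(tp1.voxels[:, :, k].T, lo, hi)
        p2 = _to_uint8(tp2.voxels[:, :, k].T, lo, hi)
        ann = np.stack([p2, p2, p2], axis=-1)
        nm = new_mask[:, :, k].T
        fm = fp_mask[:, :, k].T
        ann[nm] = (255, 0, 0)
        ann[fm] = (0, 255, 0)
        big = np.repeat(np.repeat(p2, 2, axis=0), 2, axis=1)

        canvas = np.zeros((3 * hp, 3 * wp, 3), dtype=np.uint8)
        canvas[:hp, :wp] = p1[..., None]
        canvas[:hp, wp:2 * wp] = p2[..., None]
        canvas[:hp, 2 * wp:3 * wp] = ann
        c0 = (3 * wp - 2 * wp) // 2
        canvas[hp:3 * hp, c0:c0 + 2 * wp] = big[..., None]

        ds = _base_sc_dataset(tp1.meta, series_uid, k + 1)
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
        ds.Rows, ds.Columns = canvas.shape[:2]
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelData = canvas.tobytes()
        ds.save_as(str(out_dir / f"overlay_{k:04d}.dcm"), enforce_file_format=True)
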