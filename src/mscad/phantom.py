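"""Synthetic two-timepoint T2-FLAIR-like phantoms with ground truth.

The phantom emulates what the change-detection pipeline actually consumes:
an ellipsoidal "brain" of uniform tissue intensity inside a brighter
"skull" shell (separated by a dark CSF-like gap), hyperintense spherical
lesions, a small rigid inter-timepoint head motion, a smooth multiplicative
bias field per session, and additive Gaussian noise.  Every run carries an
analytic ground-truth bundle (brain mask, per-lesion masks and categories,
the applied transform), so detection and registration can be scored without
clinical data.

Defaults are the package's reference study conditions: a 128^3 grid at 1 mm
isotropic voxels, lesion contrast 5x the noise level, 2 degrees / 3 mm of
inter-timepoint motion and a 20% bias-field amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .atlas import AtlasLabelMap
from .io_formats import VolumeImage
from .transforms import AffineTransform, RigidTransform, rotation_matrix

__all__ = [
    "Sphere",
    "PhantomSpec",
    "PhantomTruth",
    "LesionTruth",
    "generate_pair",
    "render_anatomy",
    "generate_toy_atlas",
    "write_synthetic_dicom_series",
]

_EDGE_MM = 1.0  # linear smoothing width of all phantom boundaries
_GAP_RHO = 1.10  # inner edge of the skull shell, in normalized radius
_SHELL_RHO = 1.22  # outer edge of the skull shell


@dataclass(frozen=True)
class Sphere:
    """A spherical lesion: center offset from brain center (mm), radius, contrast."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    intensity_offset: float = 30.0


def _default_preexisting() -> list[Sphere]:
    return [Sphere((-15, -20, 0), 4.0), Sphere((25, -5, -10), 3.5)]


def _default_new() -> list[Sphere]:
    return [Sphere((20, 10, 5), 3.0), Sphere((-18, 12, -8), 3.5),
            Sphere((10, -25, 6), 4.0)]


def _default_reversed() -> list[Sphere]:
    return [Sphere((0, 22, -5), 3.5)]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of a synthetic two-timepoint pair."""

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_axes: tuple[float, float, float] = (42.0, 52.0, 38.0)
    tissue_level: float = 100.0
    skull_level: float = 160.0
    lesions_tp1: tuple[Sphere, ...] = field(default_factory=lambda: tuple(_default_preexisting()))
    lesions_new: tuple[Sphere, ...] = field(default_factory=lambda: tuple(_default_new()))
    lesions_reversed: tuple[Sphere, ...] = field(default_factory=lambda: tuple(_default_reversed()))
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 2.0)
    translation_mm: tuple[float, float, float] = (2.0, -2.0, 1.0)
    bias_amplitude: float = 0.2
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape components must be >= 1")
        if min(self.spacing) <= 0:
            raise ValueError("spacing components must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must be in [0, 1)")
        axes = np.asarray(self.brain_axes, dtype=float)
        for les in (*self.lesions_tp1, *self.lesions_new, *self.lesions_reversed):
            if les.radius_mm <= 0:
                raise ValueError(f"lesion radius must be > 0: {les}")
            rho = float(np.linalg.norm(np.asarray(les.center_mm) / axes))
            if rho >= 1.0:
                raise ValueError(f"lesion center outside the brain ellipsoid: {les}")

    @property
    def center_mm(self) -> np.ndarray:
        """Physical center of the grid (== brain center)."""
        return (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.spacing)

    @property
    def inter_tp_transform(self) -> RigidTransform:
        """Rigid map through which Timepoint-2 samples the anatomy."""
        return RigidTransform.from_center(
            rotation_matrix(self.rotation_deg), self.translation_mm, self.center_mm
        )

    def without_changes(self) -> "PhantomSpec":
        """Same anatomy with no new and no reversed lesions (stable patient)."""
        return replace(self, lesions_new=(), lesions_reversed=())


@dataclass(frozen=True)
class LesionTruth:
    category: str  # 'preexisting' | 'new' | 'reversed'
    sphere: Sphere
    mask: np.ndarray  # boolean, on the Timepoint-1 grid


@dataclass(frozen=True)
class PhantomTruth:
    brain_mask: np.ndarray
    lesions: tuple[LesionTruth, ...]
    applied_transform: RigidTransform
    expected_registration: RigidTransform

    @property
    def new_lesions(self) -> list[LesionTruth]:
        return [l for l in self.lesions if l.category == "new"]

    @property
    def reversed_lesions(self) -> list[LesionTruth]:
        return [l for l in self.lesions if l.category == "reversed"]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grid_points(spec: PhantomSpec) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def _smoothstep(signed_distance_mm: np.ndarray) -> np.ndarray:
    """1 inside, 0 outside, linear ramp of width _EDGE_MM across the edge."""
    return np.clip(signed_distance_mm / _EDGE_MM + 0.5, 0.0, 1.0)


def _anatomy_values(points: np.ndarray, spec: PhantomSpec,
                    lesions: list[Sphere]) -> np.ndarray:
    center = spec.center_mm
    axes = np.asarray(spec.brain_axes, dtype=float)
    rel = (points - center) / axes
    rho = np.sqrt(np.einsum("ij,ij->i", rel, rel))
    scale = float(axes.min())  # convert normalized radius to approx. mm
    brain_w = _smoothstep((1.0 - rho) * scale)
    shell_w = _smoothstep((rho - _GAP_RHO) * scale) * _smoothstep((_SHELL_RHO - rho) * scale)
    vals = spec.tissue_level * brain_w + spec.skull_level * shell_w
    for les in lesions:
        c = center + np.asarray(les.center_mm, dtype=float)
        pad = les.radius_mm + _EDGE_MM
        # lesions are tiny relative to the grid: evaluate inside a box only
        sel = (
            (np.abs(points[:, 0] - c[0]) <= pad)
            & (np.abs(points[:, 1] - c[1]) <= pad)
            & (np.abs(points[:, 2] - c[2]) <= pad)
        )
        sub = points[sel] - c
        r = np.sqrt(np.einsum("ij,ij->i", sub, sub))
        vals[sel] += les.intensity_offset * _smoothstep(les.radius_mm - r) * brain_w[sel]
    return vals


def render_anatomy(
    spec: PhantomSpec,
    timepoint: str = "tp1",
    transform: RigidTransform | AffineTransform | None = None,
    _pts: np.ndarray | None = None,
) -> VolumeImage:
    """Noise- and bias-free anatomy, optionally sampled through a transform.

    ``timepoint`` selects the lesion content: 'tp1' has the preexisting and
    reversed-contrast lesions; 'tp2' has the preexisting and new lesions.
    The output at grid point x is the anatomy evaluated at transform(x).
    """
    pts = _grid_points(spec) if _pts is None else _pts
    if transform is not None:
        pts = transform.apply(pts)
    if timepoint == "tp1":
        lesions = [*spec.lesions_tp1, *spec.lesions_reversed]
    elif timepoint == "tp2":
        lesions = [*spec.lesions_tp1, *spec.lesions_new]
    else:
        raise ValueError("timepoint must be 'tp1' or 'tp2'")
    vals = _anatomy_values(pts, spec, lesions).reshape(spec.grid_shape)
    return VolumeImage(
        voxels=vals,
        spacing=np.asarray(spec.spacing),
        origin=np.zeros(3),
        direction=np.eye(3),
        meta={"PatientID": "PHANTOM", "timepoint": timepoint},
    )


def _bias_field(spec: PhantomSpec, rng: np.random.Generator,
                brain: np.ndarray, _pts: np.ndarray | None = None) -> np.ndarray:
    """Smooth strictly positive field: product of low-frequency cosine modes."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    pts = (_grid_points(spec) if _pts is None else _pts) - spec.center_mm
    fov = float(np.max(np.asarray(spec.grid_shape) * np.asarray(spec.spacing)))
    field_vals = np.ones(pts.shape[0])
    n_modes = 3
    amp = spec.bias_amplitude / n_modes
    for _ in range(n_modes):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        freq = rng.uniform(0.5, 1.5)  # cycles across the field of view
        phase = rng.uniform(0, 2 * np.pi)
        field_vals *= 1.0 + amp * np.cos(2 * np.pi * freq * (pts @ u) / fov + phase)
    field = field_vals.reshape(spec.grid_shape)
    return field / field[brain].mean()


def generate_pair(spec: PhantomSpec) -> tuple[VolumeImage, VolumeImage, PhantomTruth]:
    """Generate (tp1, tp2, truth); identical seeds give identical output.

    tp1 holds the preexisting and reversed-contrast lesions; tp2 the
    preexisting and new lesions, sampled through the inter-timepoint rigid
    transform.  Each timepoint gets its own bias field and noise draw.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    no_motion = (tuple(spec.rotation_deg) == (0.0, 0.0, 0.0)
                 and tuple(spec.translation_mm) == (0.0, 0.0, 0.0))
    pts = _grid_points(spec)
    tp1 = render_anatomy(spec, "tp1", _pts=pts)
    tp2 = render_anatomy(spec, "tp2",
                         None if no_motion else spec.inter_tp_transform, _pts=pts)

    center = spec.center_mm
    axes = np.asarray(spec.brain_axes, dtype=float)
    brain = (np.linalg.norm((pts - center) / axes, axis=1) < 1.0).reshape(spec.grid_shape)

    v1 = tp1.voxels * _bias_field(spec, np.random.default_rng(seeds[0]), brain, _pts=pts)
    v2 = tp2.voxels * _bias_field(spec, np.random.default_rng(seeds[1]), brain, _pts=pts)
    if spec.noise_sigma > 0:
        v1 = v1 + np.random.default_rng(seeds[2]).normal(0, spec.noise_sigma, spec.grid_shape)
        v2 = v2 + np.random.default_rng(seeds[3]).normal(0, spec.noise_sigma, spec.grid_shape)

    lesions = []
    for category, group in (
        ("preexisting", spec.lesions_tp1),
        ("new", spec.lesions_new),
        ("reversed", spec.lesions_reversed),
    ):
        for les in group:
            c = center + np.asarray(les.center_mm, dtype=float)
            sel = (
                (np.abs(pts[:, 0] - c[0]) <= les.radius_mm)
                & (np.abs(pts[:, 1] - c[1]) <= les.radius_mm)
                & (np.abs(pts[:, 2] - c[2]) <= les.radius_mm)
            )
            sub = pts[sel] - c
            mask_flat = np.zeros(pts.shape[0], dtype=bool)
            mask_flat[sel] = np.einsum("ij,ij->i", sub, sub) <= les.radius_mm**2
            lesions.append(
                LesionTruth(category=category, sphere=les,
                            mask=mask_flat.reshape(spec.grid_shape))
            )

    applied = spec.inter_tp_transform
    truth = PhantomTruth(
        brain_mask=brain,
        lesions=tuple(lesions),
        applied_transform=applied,
        expected_registration=applied.inverse(),
    )
    out1 = tp1.with_voxels(v1)
    out1.meta.update({"StudyInstanceUID": "1.2.826.0.1.3680043.9999.1",
                      "session": "timepoint-1", "seed": str(spec.seed)})
    out2 = tp2.with_voxels(v2)
    out2.meta.update({"StudyInstanceUID": "1.2.826.0.1.3680043.9999.1",
                      "session": "timepoint-2", "seed": str(spec.seed)})
    return out1, out2, truth


# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------

def generate_toy_atlas(
    n_regions: int,
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    brain_axes: tuple[float, float, float] = (42.0, 52.0, 38.0),
) -> AtlasLabelMap:
    """Partition the brain ellipsoid into ``n_regions`` contiguous blocks.

    Stands in for a full anatomical atlas: every brain voxel gets a nonzero
    label with a generated region name, every non-brain voxel is 0.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    spec = PhantomSpec(grid_shape=grid_shape, spacing=spacing, brain_axes=brain_axes,
                       lesions_tp1=(), lesions_new=(), lesions_reversed=())
    pts = _grid_points(spec)
    axes = np.asarray(brain_axes, dtype=float)
    brain = np.linalg.norm((pts - spec.center_mm) / axes, axis=1) < 1.0
    n_brain = int(brain.sum())
    if n_regions > n_brain:
        raise ValueError(f"n_regions={n_regions} exceeds brain voxel count {n_brain}")
    labels_flat = np.zeros(pts.shape[0], dtype=np.int32)
    # brain voxels in lexicographic index order, split into equal chunks
    brain_idx = np.flatnonzero(brain)
    chunks = np.array_split(brain_idx, n_regions)
    for region_id, chunk in enumerate(chunks, start=1):
        labels_flat[chunk] = region_id
    labels = VolumeImage(
        voxels=labels_flat.reshape(grid_shape),
        spacing=np.asarray(spacing),
        origin=np.zeros(3),
        direction=np.eye(3),
        meta={"description": "synthetic toy atlas"},
    )
    names = {i: f"synthetic region {i:03d}" for i in range(1, n_regions + 1)}
    return AtlasLabelMap(labels=labels, names=names)


# ---------------------------------------------------------------------------
# synthetic DICOM series
# ---------------------------------------------------------------------------

def write_synthetic_dicom_series(v: VolumeImage, out_dir,
                                 series_uid: str | None = None) -> None:
    """Write ``v`` as one MR-storage DICOM file per axial slice.

    Intensities are quantized to 16 bits with a rescale slope/intercept, so
    reading the series back reproduces the voxels to within the (tiny)
    quantization step.  Geometry tags encode the volume's spacing, origin
    and axis directions in the DICOM (LPS) convention.
    """
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise IOError(f"parent directory does not exist: {out_dir.parent}")
    out_dir.mkdir(exist_ok=True)

    vox = np.asarray(v.voxels, dtype=float)
    vmin, vmax = float(vox.min()), float(vox.max())
    scale = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
    stored = np.rint((vox - vmin) / scale).astype(np.uint16)

    lps = np.diag([-1.0, -1.0, 1.0])
    dir_lps = lps @ v.direction
    origin_lps = lps @ v.origin
    row_dir, col_dir, normal = dir_lps[:, 0], dir_lps[:, 1], dir_lps[:, 2]

    series_uid = series_uid or generate_uid()
    study_uid = v.meta.get("StudyInstanceUID", generate_uid())
    nx, ny, nz = v.shape
    for k in range(nz):
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = MRImageStorage
        file_meta.MediaStorageSOPInstanceUID = generate_uid()
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=file_meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "MR"
        ds.PatientID = str(v.meta.get("PatientID", "PHANTOM"))
        ds.PatientName = str(v.meta.get("PatientName", "PHANTOM"))
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = "synthetic T2-FLAIR"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [f"{x:.8f}" for x in (*row_dir, *col_dir)]
        pos = origin_lps + k * v.spacing[2] * normal
        ds.ImagePositionPatient = [f"{x:.8f}" for x in pos]
        ds.PixelSpacing = [f"{v.spacing[1]:.8f}", f"{v.spacing[0]:.8f}"]
        ds.SliceThickness = f"{v.spacing[2]:.8f}"
        ds.SpacingBetweenSlices = f"{v.spacing[2]:.8f}"
        ds.RescaleSlope = f"{scale:.10g}"[:16]
        ds.RescaleIntercept = f"{vmin:.10g}"[:16]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        ds.save_as(str(out_dir / f"slice_{k:04d}.dcm"), enforce_file_format=True)
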