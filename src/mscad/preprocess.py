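"""Bring two timepoints into a common, comparable space.

Admission checks, resolution harmonization (downsample the higher-resolution
scan onto the lower-resolution grid), rigid registration, classical brain
extraction, polynomial bias-field correction, and quantile histogram
matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from ._registration import RegistrationSettings, resample_onto, run_registration
from .errors import DegenerateHistogramError, ExtractionError, GeometryError
from .io_formats import VolumeImage
from .transforms import RigidTransform

__all__ = [
    "AdmissionVerdict",
    "BrainMask",
    "check_admissible",
    "harmonize_resolution",
    "register_rigid",
    "extract_brain",
    "erode_mask",
    "correct_bias_field",
    "match_histograms",
]

# Slice thickness at or above this is clinically unusable for the CAD.
ADMISSION_LIMIT_MM = 5.0
# Below the hard limit but at/above this the scan is flagged low-resolution.
LOW_RESOLUTION_MM = 3.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class AdmissionVerdict:
    accepted: bool
    reason: str
    low_resolution: bool = False

    def __bool__(self) -> bool:
        return self.accepted


def check_admissible(v: VolumeImage) -> AdmissionVerdict:
    """Reject scans whose largest voxel dimension is >= 5 mm.

    Scans under the limit but with coarse out-of-plane resolution are
    accepted with a low-resolution flag.
    """
    worst = float(np.max(v.spacing))
    if worst >= ADMISSION_LIMIT_MM:
        return AdmissionVerdict(
            False,
            f"slice thickness {worst:g} mm >= {ADMISSION_LIMIT_MM:g} mm limit",
        )
    if worst >= LOW_RESOLUTION_MM:
        return AdmissionVerdict(True, f"accepted; low resolution ({worst:g} mm)", True)
    return AdmissionVerdict(True, "accepted")


@dataclass
class BrainMask:
    """Binary brain mask co-indexed with a :class:`VolumeImage` grid.

    Exactly one 26-connected foreground component, nonempty.
    """

    mask: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.mask.ndim != 3:
            raise GeometryError("brain mask must be 3-D")
        if not self.mask.any():
            raise ExtractionError("brain mask is empty")
        _, n = ndi.label(self.mask, structure=_STRUCT_26)
        if n != 1:
            raise ExtractionError(f"brain mask has {n} 26-connected components")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))


def harmonize_resolution(
    a: VolumeImage, b: VolumeImage
) -> tuple[VolumeImage, VolumeImage]:
    """Resample the higher-resolution scan onto the lower-resolution grid.

    Resolution is compared by voxel volume; ties keep the first input's
    (Timepoint-1) grid.  Identical grids pass through unchanged.  Intensity
    resampling is linear — downsampling toward the coarser grid avoids the
    interpolation artifacts of upsampling the coarse scan.
    """
    if a.same_grid(b):
        return a, b
    va, vb = a.voxel_volume_mm3, b.voxel_volume_mm3
    if vb > va:  # b is coarser: bring a onto b's grid
        return resample_onto(a, b), b
    return a, resample_onto(b, a)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    settings: RegistrationSettings | None = None,
) -> tuple[RigidTransform, VolumeImage]:
    """Rigidly register ``moving`` to ``fixed`` (mutual information).

    Returns the transform (fixed-space points -> moving-space points) and
    the moving image resampled onto the fixed grid.  Bitwise-identical
    inputs register as the exact identity without optimization.
    """
    if moving.same_grid(fixed) and np.array_equal(moving.voxels, fixed.voxels):
        return RigidTransform.identity(), moving.with_voxels(moving.voxels.copy())
    tx, _metric = run_registration(moving, fixed, "rigid", settings)
    resampled = resample_onto(moving, fixed, tx)
    return tx, resampled


def extract_brain(v: VolumeImage, closing_radius: int = 2) -> BrainMask:
    """Skull-strip by Otsu thresholding and morphology.

    Otsu foreground threshold, largest 26-connected component, binary
    closing (ball of ``closing_radius`` voxels) and hole filling, so the
    mask is a single solid component.  Restricting the downstream analysis
    to brain parenchyma suppresses false positives from non-brain tissue.
    """
    vox = np.asarray(v.voxels, dtype=float)
    if np.ptp(vox) == 0:
        raise ExtractionError("constant-intensity volume: no foreground to extract")
    thr = threshold_otsu(vox)
    fg = vox > thr
    if not fg.any():
        raise ExtractionError("no voxels above the foreground threshold")
    labels, n = ndi.label(fg, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=ball(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    # closing can merge nothing but guard the single-component invariant
    labels, n = ndi.label(mask, structure=_STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return BrainMask(mask=mask, spacing=v.spacing.copy())


def erode_mask(m: BrainMask, margin_voxels: int) -> BrainMask:
    """Shrink the mask by ``margin_voxels`` to trim boundary artifacts."""
    if margin_voxels <= 0:
        return m
    eroded = ndi.binary_erosion(m.mask, structure=ball(margin_voxels))
    if not eroded.any():
        raise ExtractionError("mask erosion removed all voxels")
    labels, n = ndi.label(eroded, structure=_STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        eroded = labels == int(np.argmax(counts))
    return BrainMask(mask=eroded, spacing=m.spacing.copy())


def _monomial_exponents(order: int) -> list[tuple[int, int, int]]:
    return [
        (a, b, c)
        for a in range(order + 1)
        for b in range(order + 1 - a)
        for c in range(order + 1 - a - b)
    ]


def _axis_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    return [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]


def _design_at(points_ijk: tuple[np.ndarray, ...], shape, order: int) -> np.ndarray:
    """Monomial basis x^a y^b z^c (a+b+c <= order) at the given voxel indices."""
    axes = _axis_coords(shape)
    x, y, z = (axes[d][points_ijk[d]] for d in range(3))
    px = [x ** a for a in range(order + 1)]
    py = [y ** b for b in range(order + 1)]
    pz = [z ** c for c in range(order + 1)]
    return np.stack(
        [px[a] * py[b] * pz[c] for a, b, c in _monomial_exponents(order)], axis=1
    )


def _evaluate_field(coef: np.ndarray, shape, order: int) -> np.ndarray:
    """Evaluate the fitted polynomial on the full grid via broadcasting."""
    ax = _axis_coords(shape)
    px = [(ax[0] ** a)[:, None, None] for a in range(order + 1)]
    py = [(ax[1] ** b)[None, :, None] for b in range(order + 1)]
    pz = [(ax[2] ** c)[None, None, :] for c in range(order + 1)]
    out = np.zeros(shape)
    for w, (a, b, c) in zip(coef, _monomial_exponents(order)):
        out += w * (px[a] * py[b] * pz[c])
    return out


def correct_bias_field(
    v: VolumeImage, mask: BrainMask, order: int = 3
) -> VolumeImage:
    """Remove smooth multiplicative intensity inhomogeneity.

    Fits an order-``order`` 3-D polynomial to the log-intensities inside the
    mask, exponentiates it into a strictly positive low-frequency field,
    divides it out, and rescales so the mean intensity inside the mask is
    preserved.
    """
    if v.voxels.shape != mask.mask.shape:
        raise GeometryError("mask and volume grids differ")
    vox = np.asarray(v.voxels, dtype=float)
    inside = mask.mask & (vox > 0)
    if not inside.any():
        raise ExtractionError("no positive intensities inside the mask")
    # fit on reliable signal only: partial-volume voxels at the mask edge
    # are strong log-domain outliers and would tilt the field
    median = float(np.median(vox[inside]))
    core = ndi.binary_erosion(mask.mask, structure=ball(2))
    fit_sel = core & (vox > 0.5 * median)
    if not fit_sel.any():
        fit_sel = inside

    design = _design_at(np.nonzero(fit_sel), vox.shape, order)
    coef, *_ = np.linalg.lstsq(design, np.log(vox[fit_sel]), rcond=None)
    log_field = _evaluate_field(coef, vox.shape, order)
    # keep the field bounded away from zero outside the fitted region
    field = np.exp(np.clip(log_field - log_field[mask.mask].mean(), -3.0, 3.0))

    corrected = vox / field
    mean_in = vox[mask.mask].mean()
    mean_out = corrected[mask.mask].mean()
    if mean_out > 0:
        corrected *= mean_in / mean_out
    return v.with_voxels(corrected)


def match_histograms(
    moving: VolumeImage,
    reference: VolumeImage,
    mask: BrainMask,
    n_landmarks: int = 101,
) -> VolumeImage:
    """Map ``moving`` intensities onto the reference distribution.

    Quantile landmarks (percentiles 0..100) are computed inside the brain
    mask for both images and joined by a monotone piecewise-linear mapping.
    Voxels outside the mask are passed through unchanged — only the masked
    region takes part in the subtraction downstream.
    """
    if not moving.same_grid(reference):
        raise GeometryError("histogram matching requires a shared grid")
    if moving.voxels.shape != mask.mask.shape:
        raise GeometryError("mask and volume grids differ")
    ref_vals = np.asarray(reference.voxels, dtype=float)[mask.mask]
    if np.ptp(ref_vals) == 0:
        raise DegenerateHistogramError("reference is constant inside the mask")
    mov = np.asarray(moving.voxels, dtype=float)
    qs = np.linspace(0.0, 100.0, n_landmarks)
    mq = np.percentile(mov[mask.mask], qs)
    rq = np.percentile(ref_vals, qs)
    out = mov.copy()
    out[mask.mask] = np.interp(mov[mask.mask], mq, rq)
    return moving.with_voxels(out)
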