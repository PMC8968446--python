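"""SimpleITK-backed intensity registration shared by preprocess and atlas.

Normalized (Mattes) mutual information, 3-level multi-resolution pyramid,
regular-step gradient descent with physical-shift parameter scaling.  The
metric sampling is pseudo-random but seeded, so registration is
deterministic for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import RegistrationError
from .io_formats import VolumeImage
from .transforms import AffineTransform, RigidTransform

__all__ = ["RegistrationSettings", "run_registration", "resample_onto"]


@dataclass(frozen=True)
class RegistrationSettings:
    """Multi-resolution registration configuration.

    shrink_factors / smoothing_sigmas define the pyramid (coarse to fine);
    sampling_fraction is the fraction of voxels used for the metric at each
    iteration; seed makes the sampling reproducible.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    iterations: int = 300
    sampling_fraction: float = 0.05
    min_samples: int = 50000  # floor on metric samples for small volumes
    histogram_bins: int = 32
    learning_rate: float = 1.0
    # gentler steps for affine: it starts from a moment-matched initial
    # transform and large coarse-level steps can leave that basin
    affine_learning_rate: float = 0.2
    min_step: float = 1e-6
    relaxation_factor: float = 0.6
    seed: int = 12345

    def __post_init__(self):
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ValueError("shrink_factors and smoothing_sigmas lengths differ")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling_fraction must be in (0, 1]")


def _physical_bounds(v: VolumeImage) -> tuple[np.ndarray, np.ndarray]:
    shape = np.asarray(v.shape) - 1
    corners = np.array(
        [[i, j, k] for i in (0, shape[0]) for j in (0, shape[1]) for k in (0, shape[2])],
        dtype=float,
    )
    pts = v.index_to_physical(corners)
    return pts.min(axis=0), pts.max(axis=0)


def _check_overlap(fixed: VolumeImage, moving: VolumeImage) -> None:
    flo, fhi = _physical_bounds(fixed)
    mlo, mhi = _physical_bounds(moving)
    if np.any(fhi < mlo) or np.any(mhi < flo):
        raise RegistrationError("fields of view do not overlap; no shared anatomy")


def _intensity_moments(v: VolumeImage) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-weighted centroid (mm) and per-axis spread of the foreground."""
    vox = np.asarray(v.voxels, dtype=float)
    w = np.clip(vox - np.percentile(vox, 50), 0, None)
    total = w.sum()
    if total <= 0:
        w = np.ones_like(vox)
        total = w.size
    idx = np.indices(vox.shape, dtype=float)
    centroid_idx = np.array([(idx[d] * w).sum() / total for d in range(3)])
    var_idx = np.array(
        [((idx[d] - centroid_idx[d]) ** 2 * w).sum() / total for d in range(3)]
    )
    spacing = np.asarray(v.spacing)
    center_mm = v.index_to_physical(centroid_idx)
    spread_mm = np.sqrt(var_idx) * spacing
    return np.asarray(center_mm), spread_mm


def _to_matrix_form(tx: sitk.Transform) -> tuple[np.ndarray, np.ndarray]:
    """Flatten an ITK matrix-offset transform (with center) to A, b."""
    a = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    return a, t + c - a @ c


def run_registration(
    moving: VolumeImage,
    fixed: VolumeImage,
    kind: str,
    settings: RegistrationSettings | None = None,
) -> tuple[RigidTransform | AffineTransform, float]:
    """Register ``moving`` onto ``fixed``; returns (transform, final metric).

    The transform maps fixed-space physical points to moving-space physical
    points (the resampling convention).  ``kind`` is 'rigid' or 'affine'.
    """
    settings = settings or RegistrationSettings()
    _check_overlap(fixed, moving)

    fimg = fixed.to_sitk()
    mimg = moving.to_sitk()

    if kind == "rigid":
        initial = sitk.CenteredTransformInitializer(
            fimg, mimg, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
    elif kind == "affine":
        # moment-based start: match intensity centroids and per-axis spread,
        # so the scale begins near its true value (MI alone has a mirror
        # optimum for smooth, textureless shapes)
        c_fix, s_fix = _intensity_moments(fixed)
        c_mov, s_mov = _intensity_moments(moving)
        initial = sitk.AffineTransform(3)
        initial.SetCenter(tuple(float(x) for x in c_fix))
        initial.SetMatrix(tuple(float(x) for x in np.diag(s_mov / s_fix).ravel()))
        initial.SetTranslation(tuple(float(x) for x in (c_mov - c_fix)))
    else:
        raise ValueError(f"unknown registration kind: {kind}")

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(settings.histogram_bins)
    n_voxels = int(np.prod(fixed.shape))
    fraction = max(settings.sampling_fraction,
                   min(1.0, settings.min_samples / n_voxels))
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(fraction, settings.seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=(settings.learning_rate if kind == "rigid"
                      else settings.affine_learning_rate),
        minStep=settings.min_step,
        numberOfIterations=settings.iterations,
        relaxationFactor=settings.relaxation_factor,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(settings.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(settings.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)

    try:
        result = reg.Execute(fimg, mimg)
    except RuntimeError as exc:
        raise RegistrationError(f"registration failed: {exc}") from exc
    metric = float(reg.GetMetricValue())

    a, b = _to_matrix_form(
        sitk.Euler3DTransform(result) if kind == "rigid" else sitk.AffineTransform(result)
    )
    if kind == "rigid":
        # Re-orthonormalize against accumulated float drift before validation.
        u, _, vt = np.linalg.svd(a)
        tx = RigidTransform(u @ vt, b)
    else:
        tx = AffineTransform(a, b)
    return tx, metric


def resample_onto(
    moving: VolumeImage,
    fixed: VolumeImage,
    transform: RigidTransform | AffineTransform | None = None,
    interpolation: str = "linear",
    default_value: float = 0.0,
) -> VolumeImage:
    """Resample ``moving`` onto the grid of ``fixed`` through ``transform``.

    ``transform`` maps fixed-space points into moving-space points; identity
    when omitted.  ``interpolation`` is 'linear' or 'nearest'.
    """
    tx = sitk.AffineTransform(3)
    if transform is not None:
        m = transform.rotation if isinstance(transform, RigidTransform) else transform.matrix
        tx.SetMatrix(tuple(float(x) for x in m.ravel()))
        tx.SetTranslation(tuple(float(x) for x in transform.translation))
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        moving.to_sitk(), fixed.to_sitk(), tx, interp, float(default_value),
        sitk.sitkFloat64,
    )
    res = VolumeImage.from_sitk(out, meta=dict(moving.meta))
    return res
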