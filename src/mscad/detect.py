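"""Temporal subtraction and lesion-candidate extraction.

New lesions appear as positive residuals in the Timepoint-2 minus
Timepoint-1 difference map.  Candidates are suprathreshold 26-connected
components; the center-of-gravity intensity rule then rejects candidates
that are brighter at Timepoint-1 (misregistration artifacts) as false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import scipy.ndimage as ndi

from .errors import GeometryError
from .io_formats import Geometry, VolumeImage
from .preprocess import BrainMask

__all__ = [
    "CandidateStatus",
    "DifferenceMap",
    "LesionCandidate",
    "subtract",
    "extract_candidates",
    "classify_candidate",
    "quantify",
]


class CandidateStatus(Enum):
    UNCLASSIFIED = "unclassified"
    NEW_LESION = "new_lesion"
    FALSE_POSITIVE = "false_positive"


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndi.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


@dataclass
class DifferenceMap:
    """Signed Timepoint-2 minus Timepoint-1 intensities, zero outside the mask."""

    delta: np.ndarray
    mask: BrainMask
    geometry: Geometry

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != self.mask.mask.shape:
            raise GeometryError("difference map and mask grids differ")
        if np.any(self.delta[~self.mask.mask] != 0):
            raise GeometryError("difference map must be zero outside the mask")


@dataclass
class LesionCandidate:
    """A 26-connected cluster of suprathreshold difference-map voxels.

    ``voxel_indices`` is an (n, 3) integer array; ``cog`` the rounded
    arithmetic centroid; ``volume_mm3`` the cluster's physical volume.
    """

    voxel_indices: np.ndarray
    cog: tuple[int, int, int]
    volume_mm3: float
    peak_delta: float
    geometry: Geometry
    status: CandidateStatus = CandidateStatus.UNCLASSIFIED
    region: str | None = field(default=None)

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.voxel_indices.ndim != 2 or self.voxel_indices.shape[1] != 3:
            raise ValueError("voxel_indices must have shape (n, 3)")
        if len(self.voxel_indices) == 0:
            raise ValueError("candidate voxel set is empty")
        lo = self.voxel_indices.min(axis=0)
        hi = self.voxel_indices.max(axis=0)
        if np.any(np.asarray(self.cog) < lo) or np.any(np.asarray(self.cog) > hi):
            raise ValueError("center of gravity outside the candidate bounding box")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def is_new_lesion(self) -> bool:
        return self.status is CandidateStatus.NEW_LESION

    @property
    def cog_mm(self) -> np.ndarray:
        return self.geometry.index_to_physical(np.asarray(self.cog, dtype=float))


def subtract(tp2: VolumeImage, tp1: VolumeImage, mask: BrainMask) -> DifferenceMap:
    """Voxelwise tp2 - tp1 inside the brain mask, zero outside."""
    if not tp2.same_grid(tp1):
        raise GeometryError("subtraction requires both timepoints on one grid")
    if tp1.voxels.shape != mask.mask.shape:
        raise GeometryError("mask grid differs from the image grid")
    delta = np.where(
        mask.mask,
        np.asarray(tp2.voxels, dtype=float) - np.asarray(tp1.voxels, dtype=float),
        0.0,
    )
    return DifferenceMap(delta=delta, mask=mask, geometry=tp1.geometry)


def extract_candidates(
    d: DifferenceMap,
    k: float = 3.0,
    min_volume: float = 15.0,
    connectivity: int = 26,
) -> list[LesionCandidate]:
    """Threshold the difference map at mu + k*sigma and split into clusters.

    mu and sigma are the in-mask mean and standard deviation of the
    difference map.  Connected components (default 26-connectivity) smaller
    than ``min_volume`` mm^3 are discarded.  A flat map (sigma == 0) yields
    an empty list.
    """
    inside = d.delta[d.mask.mask]
    mu = float(inside.mean())
    sigma = float(inside.std())
    if sigma == 0.0:
        return []
    thr = mu + k * sigma
    supra = (d.delta > thr) & d.mask.mask
    labels, n = ndi.label(supra, structure=_structure(connectivity))
    if n == 0:
        return []
    voxel_volume = float(np.prod(np.asarray(d.geometry.spacing)))
    candidates: list[LesionCandidate] = []
    objects = ndi.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        local = labels[slc] == lab
        idx = np.argwhere(local) + np.array([s.start for s in slc])
        vol = len(idx) * voxel_volume
        if vol < min_volume:
            continue
        centroid = idx.mean(axis=0)
        cog = np.rint(centroid).astype(int)
        cog = np.clip(cog, idx.min(axis=0), idx.max(axis=0))
        candidates.append(
            LesionCandidate(
                voxel_indices=idx,
                cog=tuple(int(c) for c in cog),
                volume_mm3=vol,
                peak_delta=float(d.delta[idx[:, 0], idx[:, 1], idx[:, 2]].max()),
                geometry=d.geometry,
            )
        )
    candidates.sort(key=lambda c: tuple(c.voxel_indices[0]))
    return candidates


def classify_candidate(
    c: LesionCandidate, tp1: VolumeImage, tp2: VolumeImage
) -> LesionCandidate:
    """Apply the center-of-gravity false-positive rule.

    The candidate is a false positive iff the intensity at its center of
    gravity is higher at Timepoint-1 than at Timepoint-2; otherwise it is a
    new lesion.  Ties count as new lesions, keeping the sensitivity-first
    bias: false positives are cheap to discard at human review, missed
    lesions are not.
    """
    cog = np.asarray(c.cog)
    for v in (tp1, tp2):
        if np.any(cog < 0) or np.any(cog >= np.asarray(v.shape)):
            raise GeometryError(f"center of gravity {tuple(cog)} outside grid {v.shape}")
    i1 = float(tp1.voxels[c.cog])
    i2 = float(tp2.voxels[c.cog])
    status = (
        CandidateStatus.FALSE_POSITIVE if i1 > i2 else CandidateStatus.NEW_LESION
    )
    return replace(c, status=status)


def quantify(c: LesionCandidate, spacing=None) -> float:
    """Physical volume in mm^3: voxel count times voxel volume."""
    if spacing is None:
        spacing = np.asarray(c.geometry.spacing)
    spacing = np.asarray(spacing, dtype=float)
    return float(len(c.voxel_indices) * np.prod(spacing))
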