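"""Anatomical labeling of detected lesions through an atlas.

The subject space is affinely registered (12 degrees of freedom, same
mutual-information objective as the rigid step) to an atlas reference, and
each new lesion's center of gravity is looked up in the atlas label volume
to name its approximate anatomical location.

The atlas is an input artifact: a label volume (NIfTI) plus a two-column
TSV table mapping label ids to region names; label 0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._registration import RegistrationSettings, run_registration
from .detect import LesionCandidate
from .errors import GeometryError
from .io_formats import VolumeImage, read_volume
from .transforms import AffineTransform

__all__ = [
    "AtlasLabelMap",
    "load_atlas",
    "save_atlas",
    "register_affine_to_atlas",
    "label_lesion",
]

UNLABELED = "unlabeled"


@dataclass
class AtlasLabelMap:
    """Integer label grid with geometry plus an id -> region-name table."""

    labels: VolumeImage
    names: dict[int, str]

    def __post_init__(self):
        grid_ids = np.unique(np.asarray(self.labels.voxels).astype(int))
        missing = [int(i) for i in grid_ids if i != 0 and int(i) not in self.names]
        if missing:
            raise ValueError(f"label ids present in grid but not in names: {missing[:10]}")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def region_at_index(self, index) -> str:
        idx = np.asarray(index, dtype=int)
        shape = np.asarray(self.labels.shape)
        if np.any(idx < 0) or np.any(idx >= shape):
            return UNLABELED
        label = int(self.labels.voxels[tuple(idx)])
        return self.names.get(label, UNLABELED) if label != 0 else UNLABELED


def load_atlas(labels_path, names_path) -> AtlasLabelMap:
    """Load a label NIfTI and a two-column (id, name) TSV."""
    labels = read_volume(labels_path)
    labels.voxels = np.rint(labels.voxels).astype(int)
    table = pd.read_csv(names_path, sep="\t", header=None, names=["id", "name"],
                        comment="#")
    # tolerate an optional header row
    if not str(table.iloc[0, 0]).lstrip("-").isdigit():
        table = table.iloc[1:]
    names = {int(r.id): str(r.name) for r in table.itertuples()}
    return AtlasLabelMap(labels=labels, names=names)


def save_atlas(atlas: AtlasLabelMap, labels_path, names_path) -> None:
    from .io_formats import write_volume

    write_volume(atlas.labels.with_voxels(atlas.labels.voxels.astype(np.float32)),
                 labels_path)
    with open(names_path, "w") as fh:
        for label_id in sorted(atlas.names):
            fh.write(f"{label_id}\t{atlas.names[label_id]}\n")


def register_affine_to_atlas(
    subject: VolumeImage,
    atlas_ref: VolumeImage,
    settings: RegistrationSettings | None = None,
) -> AffineTransform:
    """Affine transform mapping subject physical points into atlas space."""
    # fixed=subject so the returned fixed->moving map is subject->atlas
    tx, _metric = run_registration(atlas_ref, subject, "affine", settings)
    return tx


def label_lesion(
    c: LesionCandidate, t: AffineTransform, atlas: AtlasLabelMap
) -> str:
    """Name the atlas region at the lesion's center of gravity.

    The cog is mapped through ``t`` into atlas physical space and looked up
    with nearest-neighbor rounding; background and out-of-grid points map
    to ``"unlabeled"``.
    """
    if t is None:
        raise GeometryError("affine transform required for atlas labeling")
    point_atlas = t.apply(c.cog_mm)
    idx = np.rint(atlas.labels.physical_to_index(point_atlas)).astype(int)
    return atlas.region_at_index(idx)
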