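"""End-to-end orchestration of the change-detection workflow.

Stage order: read -> admission -> resolution harmonization -> rigid
registration (Timepoint-2 onto Timepoint-1) -> brain extraction (on the
Timepoint-1 grid) -> bias-field correction (both) -> histogram matching
(Timepoint-2 onto Timepoint-1) -> subtraction -> candidate extraction ->
center-of-gravity classification -> atlas labeling (new lesions) ->
report assembly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import atlas as atlas_mod
from ._registration import RegistrationSettings
from .detect import classify_candidate, extract_candidates, subtract
from .errors import AdmissionError, MscadError, PipelineStageError
from .io_formats import VolumeImage, export_overlay_dicom, read_volume
from .preprocess import (
    check_admissible,
    correct_bias_field,
    erode_mask,
    extract_brain,
    harmonize_resolution,
    match_histograms,
    register_rigid,
)
from .report import LesionReport, build_report, render_report_text

__all__ = ["PipelineConfig", "run_pair", "STAGE_ORDER"]

STAGE_ORDER = (
    "read",
    "admission",
    "harmonize_resolution",
    "register_rigid",
    "extract_brain",
    "correct_bias_field",
    "match_histograms",
    "subtract",
    "extract_candidates",
    "classify",
    "atlas_label",
    "report",
)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; serializable as JSON or YAML.

    threshold_k and min_volume_mm3 control candidate extraction;
    mask_erosion_voxels trims the brain-mask boundary before subtraction to
    suppress misregistration residuals at the parenchyma edge.
    """

    threshold_k: float = 3.0
    min_volume_mm3: float = 15.0
    connectivity: int = 26
    mask_erosion_voxels: int = 2
    registration_shrink_factors: tuple[int, ...] = (4, 2, 1)
    registration_smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    registration_iterations: int = 300
    registration_sampling_fraction: float = 0.05
    bias_order: int = 3
    histogram_landmarks: int = 101
    brain_closing_radius: int = 2
    atlas_labels_path: str | None = None
    atlas_names_path: str | None = None
    atlas_reference_path: str | None = None
    out_dir: str | None = None
    write_overlays: bool = True
    seed: int = 12345

    def __post_init__(self):
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if self.min_volume_mm3 < 0:
            raise ValueError("min_volume_mm3 must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.mask_erosion_voxels < 0:
            raise ValueError("mask_erosion_voxels must be >= 0")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be in [0, 2^31)")
        self.registration_shrink_factors = tuple(self.registration_shrink_factors)
        self.registration_smoothing_sigmas = tuple(self.registration_smoothing_sigmas)

    @property
    def registration_settings(self) -> RegistrationSettings:
        return RegistrationSettings(
            shrink_factors=self.registration_shrink_factors,
            smoothing_sigmas=self.registration_smoothing_sigmas,
            iterations=self.registration_iterations,
            sampling_fraction=self.registration_sampling_fraction,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["registration_shrink_factors"] = list(self.registration_shrink_factors)
        d["registration_smoothing_sigmas"] = list(self.registration_smoothing_sigmas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


class _StageLog:
    def __init__(self):
        self.stages: list[dict] = []

    def run(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except (AdmissionError, PipelineStageError):
            raise
        except MscadError as exc:
            raise PipelineStageError(name, exc) from exc
        self.stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4)})
        return result


def _load(v) -> VolumeImage:
    return v if isinstance(v, VolumeImage) else read_volume(v)


def run_pair(tp1, tp2, config: PipelineConfig | None = None) -> LesionReport:
    """Run the full workflow on a Timepoint-1 / Timepoint-2 pair.

    ``tp1`` and ``tp2`` may be paths (NIfTI file or DICOM directory) or
    in-memory :class:`VolumeImage` objects.  Raises
    :class:`~mscad.errors.AdmissionError` if either scan fails the slice
    thickness rule.  When an output directory is configured, the text
    report, a JSON sidecar and the overlay DICOM series are written there.
    """
    config = config or PipelineConfig()
    log = _StageLog()

    vol1, vol2 = log.run("read", lambda: (_load(tp1), _load(tp2)))

    def _admit():
        for name, v in (("Timepoint-1", vol1), ("Timepoint-2", vol2)):
            verdict = check_admissible(v)
            if not verdict:
                raise AdmissionError(f"{name} rejected: {verdict.reason}")
        return True

    log.run("admission", _admit)

    vol1h, vol2h = log.run("harmonize_resolution", harmonize_resolution, vol1, vol2)
    rigid, vol2r = log.run(
        "register_rigid", register_rigid, vol2h, vol1h,
        settings=config.registration_settings,
    )
    mask = log.run("extract_brain", extract_brain, vol1h,
                   closing_radius=config.brain_closing_radius)
    vol1c, vol2c = log.run(
        "correct_bias_field",
        lambda: (
            correct_bias_field(vol1h, mask, order=config.bias_order),
            correct_bias_field(vol2r, mask, order=config.bias_order),
        ),
    )
    vol2m = log.run("match_histograms", match_histograms, vol2c, vol1c, mask,
                    n_landmarks=config.histogram_landmarks)

    def _subtract():
        sub_mask = erode_mask(mask, config.mask_erosion_voxels)
        return subtract(vol2m, vol1c, sub_mask)

    diff = log.run("subtract", _subtract)
    candidates = log.run(
        "extract_candidates", extract_candidates, diff,
        k=config.threshold_k, min_volume=config.min_volume_mm3,
        connectivity=config.connectivity,
    )
    candidates = log.run(
        "classify", lambda: [classify_candidate(c, vol1c, vol2m) for c in candidates]
    )

    def _label():
        if config.atlas_labels_path is None:
            return [atlas_mod.UNLABELED] * len(candidates)
        amap = atlas_mod.load_atlas(config.atlas_labels_path, config.atlas_names_path)
        if config.atlas_reference_path is not None:
            ref = read_volume(config.atlas_reference_path)
            tx = atlas_mod.register_affine_to_atlas(
                vol1h, ref, settings=config.registration_settings
            )
        else:  # subject assumed already in atlas space
            from .transforms import AffineTransform

            tx = AffineTransform.identity()
        labels = []
        for cand in candidates:
            labels.append(
                atlas_mod.label_lesion(cand, tx, amap)
                if cand.is_new_lesion
                else atlas_mod.UNLABELED
            )
        return labels

    labels = log.run("atlas_label", _label)

    session_ids = {
        "timepoint_1": str(vol1.meta.get("source", vol1.meta.get("session", "tp1"))),
        "timepoint_2": str(vol2.meta.get("source", vol2.meta.get("session", "tp2"))),
    }
    for key in ("PatientID", "StudyInstanceUID"):
        if key in vol1.meta:
            session_ids[key] = str(vol1.meta[key])

    report = log.run("report", build_report, candidates, labels, session_ids)
    report.provenance = {
        "stages": [s["stage"] for s in log.stages],
        "timings": log.stages,
        "config": config.to_dict(),
        "rigid_rotation_deg": round(rigid.rotation_angle_deg, 4),
        "rigid_translation_mm": [round(float(x), 4) for x in rigid.translation],
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(render_report_text(report))
        report.save_json(out / "report.json")
        if config.write_overlays:
            export_overlay_dicom(vol1c, vol2m, report, out / "overlays")
    return report
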