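"""Clinical output: the draft report and the contrast-injection decision.

The verdict is positive iff at least one candidate survives the
false-positive rule as a new lesion, and gadolinium-based contrast (GBCA)
is recommended exactly for positive verdicts — the contrast-gating rule
that lets follow-up scans of stable patients skip injection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detect import CandidateStatus, LesionCandidate

__all__ = ["Finding", "LesionReport", "build_report", "render_report_text"]


@dataclass(frozen=True)
class Finding:
    """One reported lesion: region name, size and physical position."""

    region: str
    volume_mm3: float
    cog_mm: tuple[float, float, float]


@dataclass
class LesionReport:
    """Per-session clinical output.

    ``findings`` holds new lesions only; ``fp_findings`` keeps the rejected
    false positives for overlay rendering and human review.  The verdict is
    positive iff there is at least one finding, and the GBCA recommendation
    equals the verdict.
    """

    session_ids: dict
    findings: list[Finding]
    fp_findings: list[Finding]
    candidates: list[LesionCandidate] = field(default_factory=list, repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    @property
    def verdict_positive(self) -> bool:
        return len(self.findings) > 0

    @property
    def gbca_recommended(self) -> bool:
        return self.verdict_positive

    def to_json_dict(self) -> dict:
        return {
            "session_ids": {k: str(v) for k, v in self.session_ids.items()},
            "verdict": "positive" if self.verdict_positive else "negative",
            "gbca_recommended": self.gbca_recommended,
            "findings": [
                {
                    "region": f.region,
                    "volume_mm3": round(f.volume_mm3, 3),
                    "cog_mm": [round(x, 3) for x in f.cog_mm],
                }
                for f in self.findings
            ],
            "false_positives": [
                {
                    "region": f.region,
                    "volume_mm3": round(f.volume_mm3, 3),
                    "cog_mm": [round(x, 3) for x in f.cog_mm],
                }
                for f in self.fp_findings
            ],
            "provenance": self.provenance,
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))


def _finding_from_candidate(c: LesionCandidate, region: str) -> Finding:
    cog_mm = np.asarray(c.cog_mm, dtype=float)
    return Finding(
        region=region,
        volume_mm3=float(c.volume_mm3),
        cog_mm=tuple(float(x) for x in cog_mm),
    )


def build_report(
    candidates: list[LesionCandidate],
    labels: list[str],
    session_ids: dict | None = None,
) -> LesionReport:
    """Assemble the report from classified candidates and their region names.

    ``labels`` must align one-to-one with ``candidates``; new lesions become
    findings, false positives go to ``fp_findings``.
    """
    if len(candidates) != len(labels):
        raise ValueError(
            f"{len(candidates)} candidates but {len(labels)} labels"
        )
    findings, fp_findings = [], []
    for cand, label in zip(candidates, labels):
        if cand.status is CandidateStatus.UNCLASSIFIED:
            raise ValueError("all candidates must be classified before reporting")
        f = _finding_from_candidate(cand, label)
        (findings if cand.is_new_lesion else fp_findings).append(f)
    return LesionReport(
        session_ids=dict(session_ids or {}),
        findings=findings,
        fp_findings=fp_findings,
        candidates=list(candidates),
    )


def render_report_text(r: LesionReport) -> str:
    """Deterministic plain-text draft report."""
    lines = ["MS lesion change report", "======================="]
    for key in sorted(r.session_ids):
        lines.append(f"{key}: {r.session_ids[key]}")
    lines.append("")
    if r.verdict_positive:
        n = len(r.findings)
        lines.append(f"RESULT: POSITIVE - {n} new white-matter lesion(s) detected.")
        lines.append("")
        lines.append("New lesions:")
        for f in r.findings:
            lines.append(f"  - {f.region}, {round(f.volume_mm3)} mm3")
        lines.append("")
        lines.append("GBCA injection recommended: YES")
    else:
        lines.append("RESULT: NEGATIVE - no newly identified white-matter lesions.")
        lines.append("")
        lines.append("GBCA injection recommended: NO")
    if r.fp_findings:
        lines.append("")
        lines.append(
            f"Note: {len(r.fp_findings)} candidate(s) rejected as false positives "
            "(retained in overlays for review)."
        )
    lines.append("")
    return "\n".join(lines)
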