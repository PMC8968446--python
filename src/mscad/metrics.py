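"""Evaluation of the GBCA-injection decision against ground truth.

A :class:`DecisionTable` is the 2x2 cross of (contrast given / not given)
by (new lesion present / absent) over a patient cohort.  Sensitivity here
is a patient-level decision metric: of the patients with a new brain
lesion, the fraction that received contrast.

The two published evaluation cohorts of the deployed system are included
as constants: a 2-month feasibility study (141 patients) and a 3-month
follow-up validation study (632 patients).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "DecisionTable",
    "MetricsSummary",
    "compute_metrics",
    "gbca_reduction",
    "gbca_reduction_no_new_lesion",
    "tabulate_decisions",
    "FEASIBILITY_STUDY",
    "FOLLOWUP_STUDY",
]


@dataclass(frozen=True)
class DecisionTable:
    """2x2 counts of GBCA decision vs. new-lesion ground truth."""

    given_new: int
    given_nonew: int
    notgiven_new: int
    notgiven_nonew: int

    def __post_init__(self):
        for name in ("given_new", "given_nonew", "notgiven_new", "notgiven_nonew"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.given_new + self.given_nonew + self.notgiven_new + self.notgiven_nonew


# 2-month feasibility study (141 patients) and 3-month follow-up validation
# study (632 patients) of the contrast-gating protocol.
FEASIBILITY_STUDY = DecisionTable(14, 3, 4, 120)
FOLLOWUP_STUDY = DecisionTable(119, 146, 17, 350)


@dataclass(frozen=True)
class MetricsSummary:
    """Decision metrics; ``None`` marks an undefined (0/0) quantity."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]

    def as_dict(self, ndigits: int | None = None) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = v if (v is None or ndigits is None) else round(v, ndigits)
        return out


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(t: DecisionTable) -> MetricsSummary:
    """Full decision-metric battery from a 2x2 table.

    Sensitivity = given_new / (given_new + notgiven_new); specificity,
    predictive values, error rates, accuracy and F1 follow the standard
    confusion-matrix definitions with "GBCA given" as the positive call.
    Any metric with a zero denominator is reported as ``None``, never 0.
    """
    if t.total == 0:
        raise ValueError("empty decision table")
    sens = _ratio(t.given_new, t.given_new + t.notgiven_new)
    spec = _ratio(t.notgiven_nonew, t.given_nonew + t.notgiven_nonew)
    ppv = _ratio(t.given_new, t.given_new + t.given_nonew)
    npv = _ratio(t.notgiven_nonew, t.notgiven_new + t.notgiven_nonew)
    acc = _ratio(t.given_new + t.notgiven_nonew, t.total)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricsSummary(
        sensitivity=sens,
        specificity=spec,
        precision=ppv,
        recall=sens,
        ppv=ppv,
        npv=npv,
        fpr=None if spec is None else 1.0 - spec,
        fnr=None if sens is None else 1.0 - sens,
        accuracy=acc,
        f1=f1,
    )


def gbca_reduction(t: DecisionTable) -> float:
    """Fraction of patients spared injection under the CAD-gated protocol."""
    if t.total == 0:
        raise ValueError("empty decision table")
    return (t.notgiven_new + t.notgiven_nonew) / t.total


def gbca_reduction_no_new_lesion(t: DecisionTable) -> Optional[float]:
    """Fraction of patients *without* new lesions who were spared injection."""
    return _ratio(t.notgiven_nonew, t.given_nonew + t.notgiven_nonew)


def tabulate_decisions(records: Iterable[tuple[bool, bool]]) -> DecisionTable:
    """Count (gbca_given, new_lesion_truth) records into the 2x2 table."""
    gn = gnn = ngn = ngnn = 0
    for gbca_given, new_lesion in records:
        if gbca_given and new_lesion:
            gn += 1
        elif gbca_given:
            gnn += 1
        elif new_lesion:
            ngn += 1
        else:
            ngnn += 1
    return DecisionTable(gn, gnn, ngn, ngnn)
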