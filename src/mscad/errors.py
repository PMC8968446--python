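"""Exception hierarchy for the CAD pipeline.

Every stage failure maps onto one of these so the pipeline can attach the
stage name and the CLI can translate them into exit codes.
"""


class MscadError(Exception):
    """Base class for all package errors."""


class FormatError(MscadError):
    """A file could not be parsed as NIfTI-1 or DICOM."""


class AmbiguousSeriesError(FormatError):
    """A DICOM directory contains more than one series."""


class GeometryError(MscadError):
    """Inconsistent or incompatible volume geometry."""


class AdmissionError(MscadError):
    """Input scan rejected by the admission rule (slice thickness >= 5 mm)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class RegistrationError(MscadError):
    """Registration failed or did not converge.

    Carries the final similarity-metric value when available.
    """

    def __init__(self, message: str, metric_value: float | None = None):
        super().__init__(message)
        self.metric_value = metric_value


class ExtractionError(MscadError):
    """Brain extraction failed (e.g. constant or empty input)."""


class DegenerateHistogramError(MscadError):
    """Histogram matching against a constant reference."""


class PipelineStageError(MscadError):
    """Wraps any error raised inside a pipeline stage with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
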