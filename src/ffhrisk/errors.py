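"""Exception hierarchy shared across the pipeline stages."""


class FFHRiskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FFHRiskError):
    """A file violates the expected on-disk format (non-binary cell, duplicate ID, ...)."""


class ValidationError(FFHRiskError):
    """Inputs are well-formed but inconsistent with the catalog or model."""


class LookupError_(FFHRiskError):
    """A factor or node id is unknown."""


class FusionError(FFHRiskError):
    """Dempster's rule cannot combine totally conflicting sources (k = 1)."""


class StructureError(FFHRiskError):
    """A graph operation would violate acyclicity."""


class ImpossibleEvidenceError(FFHRiskError):
    """The supplied evidence has probability zero under the model."""


class SamplingBudgetError(FFHRiskError):
    """Rejection sampling cannot reach the requested sample size."""


class PipelineStageError(FFHRiskError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
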