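"""Exception hierarchy shared across the package."""


class BoldmazeError(Exception):
    """Base class for all package errors."""


class FormatError(BoldmazeError):
    """A file does not conform to the documented schema (missing columns,
    unknown tokens, unparsable values)."""


class ValidationError(BoldmazeError):
    """Data parsed fine but violates an invariant (non-monotonic time,
    out-of-bounds coordinates beyond tolerance, events outside the session)."""


class InsufficientDataError(BoldmazeError):
    """Too few observations to run the requested computation."""


class DegenerateDataError(BoldmazeError):
    """Input is constant or collinear where variation is required
    (zero variance sample, constant normalization component)."""


class DesignError(BoldmazeError):
    """A factorial design cell is empty or the model matrix is singular."""


class PipelineError(BoldmazeError):
    """A pipeline stage failed; carries the stage name and affected subjects."""

    def __init__(self, stage: str, message: str, subjects=None):
        self.stage = stage
        self.subjects = list(subjects) if subjects else []
        detail = f" [subjects: {', '.join(self.subjects)}]" if self.subjects else ""
        super().__init__(f"stage '{stage}': {message}{detail}")
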