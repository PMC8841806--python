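"""Exception hierarchy shared across the package."""


class MetabalanceError(Exception):
    """Base class for all package errors."""


class FormatError(MetabalanceError):
    """An input file violates its format contract."""


class ValidationError(MetabalanceError):
    """A domain object or parameter set violates its invariants."""


class ConvergenceError(MetabalanceError):
    """An iterative fit failed to converge within its iteration budget."""


class PipelineStageError(MetabalanceError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
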