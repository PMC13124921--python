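"""Exception hierarchy shared across the package."""


class AmyhistError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AmyhistError, ValueError):
    """A parameter value violates its contract (e.g. factor < 1)."""


class InvalidInputError(AmyhistError, ValueError):
    """Input data violates a precondition (shape mismatch, empty mask, ...)."""


class UndefinedResultError(AmyhistError, ArithmeticError):
    """The requested statistic is undefined for this input (n too small, zero variance)."""


class MissingRegionError(AmyhistError, KeyError):
    """A named region required by the scheme has no voxels / no table row."""

    def __init__(self, region: str):
        super().__init__(region)
        self.region = region

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"region '{self.region}' has no voxels"


class PipelineError(AmyhistError, RuntimeError):
    """An error raised while executing a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
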