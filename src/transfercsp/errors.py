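"""Exception hierarchy shared across the pipeline stages."""


class TransferCSPError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TransferCSPError, ValueError):
    """A parameter or precondition of an operation is invalid."""


class DataError(TransferCSPError, ValueError):
    """The data content is unusable (degenerate trials, missing classes...)."""


class FormatError(TransferCSPError, ValueError):
    """A serialized container is corrupt or missing a required field."""


class NumericalError(TransferCSPError, RuntimeError):
    """A linear-algebra step failed beyond automatic repair."""


class InterpolationError(DataError):
    """A bad channel has no usable neighbors to interpolate from."""


class PipelineStageError(TransferCSPError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
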