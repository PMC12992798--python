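"""Package-wide exception types."""


class MertopoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MertopoError):
    """An invalid configuration field; the message names the field."""


class InsufficientDataError(MertopoError):
    """Too few observations to compute a quantity."""


class GenerationError(MertopoError):
    """A synthetic-data request that cannot be satisfied."""


class StageError(MertopoError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
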