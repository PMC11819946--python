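"""Exception hierarchy shared across the pipeline."""


class BiomimQsarError(Exception):
    """Base class for all package errors."""


class SchemaError(BiomimQsarError):
    """An input table violates the expected column schema or an invariant."""


class ParseError(BiomimQsarError):
    """A cell could not be parsed; message carries row and column."""


class DomainError(BiomimQsarError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class RankError(BiomimQsarError, ValueError):
    """A design matrix is rank deficient; message names dependent columns."""


class StageError(BiomimQsarError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
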