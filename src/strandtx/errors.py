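"""Exception types shared across the package."""


class StrandtxError(Exception):
    """Base class for package errors."""


class ConfigurationError(StrandtxError):
    """A run or simulation configuration is invalid."""


class ParseError(StrandtxError):
    """An input file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StageError(StrandtxError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
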