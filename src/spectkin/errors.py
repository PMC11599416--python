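"""Exception hierarchy shared across the package."""


class SpectkinError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpectkinError, ValueError):
    """An input violates a documented invariant or precondition."""


class UnitsError(ValidationError):
    """Operands carry incompatible units tags."""


class ParseError(SpectkinError, ValueError):
    """A delimited text file could not be parsed.

    Carries the offending file and 1-based line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class FitError(SpectkinError, RuntimeError):
    """Model fitting could not be carried out at all (bad inputs)."""


class PipelineError(SpectkinError, RuntimeError):
    """A pipeline stage failed; names the stage for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
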