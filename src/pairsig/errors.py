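"""Exception types shared across the package."""


class PairsigError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PairsigError, ValueError):
    """Raised when an input object violates a documented invariant."""


class ParseError(PairsigError, ValueError):
    """Raised when an external file cannot be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
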