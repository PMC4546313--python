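"""Exception types shared across the package."""


class BloodsigError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BloodsigError):
    """A text input file violated its expected dialect.

    Carries the offending line number where one can be attributed.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(BloodsigError, ValueError):
    """An in-memory object violated a structural invariant."""


class ConfigError(BloodsigError, ValueError):
    """A simulation or pipeline configuration is infeasible."""
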