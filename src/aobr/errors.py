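"""Exception hierarchy shared across the package."""


class AOBRError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AOBRError, ValueError):
    """Invalid reactor/experiment/scenario configuration."""


class ParseError(AOBRError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedMomentsError(AOBRError, ValueError):
    """Curve moments are undefined (e.g. all-zero concentrations)."""


class InsufficientHorizonError(AOBRError, ValueError):
    """Curve does not extend far enough in dimensionless time."""


class EmptyLaneError(AOBRError, ValueError):
    """A gel lane has no positive band intensity."""


class IncompleteChainError(AOBRError, ValueError):
    """A compartment chain is missing one or more entries."""
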