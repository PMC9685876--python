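"""Exception types shared across the package."""


class TransQTLError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TransQTLError):
    """An invalid simulation or analysis configuration."""


class EmptyResultError(TransQTLError):
    """An operation produced an empty result where data is required."""


class ParseError(TransQTLError):
    """A malformed input file.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class RankDeficiencyError(TransQTLError):
    """A design/covariate matrix is rank deficient; lists suspect columns."""

    def __init__(self, message: str, columns: list[str] | None = None):
        self.columns = columns or []
        if self.columns:
            message = f"{message}: collinear columns {self.columns}"
        super().__init__(message)
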