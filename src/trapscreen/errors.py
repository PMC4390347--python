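"""Exception hierarchy for screen-analysis failures.

Every error raised on bad input data derives from :class:`TrapscreenError`
so callers can catch pipeline failures without masking programming errors.
"""


class TrapscreenError(Exception):
    """Base class for all trapscreen errors."""


class SchemaError(TrapscreenError):
    """A required column or field is missing from an input table."""


class ValidationError(TrapscreenError):
    """Input parsed but violates a dataset invariant (e.g. no 0-Gy reference)."""


class QcError(TrapscreenError):
    """A well measurement fails quality control (e.g. dead RLU > total RLU)."""


class UndefinedWellError(TrapscreenError):
    """A per-well statistic is undefined (zero total signal)."""


class DeadWellError(TrapscreenError):
    """Expression normalisation requested for a well with no live signal."""


class InsufficientNullError(TrapscreenError):
    """Too few control values to estimate a null distribution."""


class DegenerateNullError(TrapscreenError):
    """Null scale estimate is zero; Z-scores would be undefined."""


class RobustFitError(TrapscreenError):
    """RANSAC failed to reach the required consensus fraction."""


class GmtParseError(TrapscreenError):
    """Malformed line in a GMT gene-set file."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class ConfigError(TrapscreenError):
    """Invalid simulation or analysis configuration."""
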