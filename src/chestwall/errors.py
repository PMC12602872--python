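"""Exception hierarchy for the chest-wall asymmetry pipeline."""


class ChestwallError(Exception):
    """Base class for all pipeline errors."""


class OrderingError(ChestwallError):
    """Centerline abscissa is degenerate (fewer than two distinct values)."""


class FrameViolationError(ChestwallError):
    """Fixed-axis spread exceeds the slice-thickness tolerance after standardization."""


class CoverageError(ChestwallError):
    """A centerline does not span the full sampling grid."""


class UndefinedStatisticError(ChestwallError):
    """Two-sample statistic undefined (both standard deviations zero)."""


class SchemaError(ChestwallError):
    """A CSV or config file violates the expected schema."""


class ConfigError(ChestwallError):
    """Invalid pipeline or cohort configuration."""
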