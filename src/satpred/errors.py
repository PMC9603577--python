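"""Exception hierarchy for the pipeline.

All errors raised deliberately by satpred derive from :class:`SatpredError`,
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class SatpredError(Exception):
    """Base class for all satpred errors."""


class ParseError(SatpredError):
    """A text input (notation, report row, table) could not be parsed."""


class ValidationError(SatpredError):
    """An input violated a documented invariant (range, bounds, completeness)."""


class ConfigurationError(SatpredError):
    """An unknown dialect, tool name, or inconsistent configuration."""


class CalibrationError(SatpredError):
    """A synthetic-score target rate is unreachable under the configured
    score distributions and thresholds."""
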