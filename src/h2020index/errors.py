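"""Exception hierarchy shared across the pipeline.

Three broad families map onto the CLI's distinct exit codes: configuration
problems (registry / run config), parse problems (malformed input tables)
and validation problems (data that parses but violates a contract).
"""


class H2020Error(Exception):
    """Base class for all package errors."""


class ConfigurationError(H2020Error):
    """Invalid registry or run configuration."""


class ParseError(H2020Error):
    """Malformed input data (bad row, non-numeric value, missing column)."""


class ValidationError(H2020Error):
    """Well-formed data violating a pipeline contract."""


class NoDataError(ValidationError):
    """An indicator has no observed values at all."""


class DegenerateGoalpostsError(ValidationError):
    """All pooled values of an indicator are identical; min-max rescaling is undefined."""


class CountryUnscorableError(ValidationError):
    """A country has no scorable target at a reference year."""


class ZeroBaselineError(ValidationError):
    """Relative change is undefined for a zero baseline value."""
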