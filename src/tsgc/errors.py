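"""Exception hierarchy for the tsgc pipeline.

Every stage raises a subclass of :class:`TsgcError`, so callers (and the CLI)
can distinguish user-input problems from numerical failures.
"""


class TsgcError(Exception):
    """Base class for all tsgc errors."""


class SchemaError(TsgcError):
    """A required column is missing or the schema mapping is wrong."""


class ParseError(TsgcError):
    """A cell could not be parsed as the expected type."""


class IntegrityError(TsgcError):
    """The panel violates a structural invariant (gaps, duplicates, ...)."""


class DegenerateBaselineError(TsgcError):
    """A subject's first observation is zero or negative; cannot baseline-scale."""


class ConfigurationError(TsgcError):
    """An analysis configuration is invalid or inconsistent with the data."""


class FitError(TsgcError):
    """A model fit failed to converge or produce usable estimates."""


class ComparabilityError(TsgcError):
    """Fits cannot be compared (e.g. AIC across REML fits)."""


class DegenerateSeriesError(TsgcError):
    """A series is constant (zero variance) where variation is required."""


class SeriesLengthError(TsgcError):
    """A series is too short for the requested operation."""


class SelectionError(FitError):
    """Automatic order selection failed for every candidate model."""


class CompletenessError(TsgcError):
    """A per-subject result required by a later stage is missing."""
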