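"""Exception hierarchy for soilcore.

All errors derive from :class:`SoilcoreError` so callers can catch the
package's failures with one clause; validation and configuration errors
are also ``ValueError`` subclasses for ergonomic use in scripts.
"""


class SoilcoreError(Exception):
    """Base class for all soilcore errors."""


class TableValidationError(SoilcoreError, ValueError):
    """A feature table, taxonomy map, or metadata table violates its contract."""


class TableParseError(SoilcoreError, ValueError):
    """A tabular input file could not be parsed (ragged rows, non-numeric cells)."""


class ConfigurationError(SoilcoreError, ValueError):
    """A configuration object holds an invalid field value."""


class AnalysisError(SoilcoreError, ValueError):
    """An analysis precondition is not met (degenerate groups, all-zero samples)."""
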