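"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 1, ``DatasetError`` (and subclasses)
to exit code 2.
"""


class SegtrendsError(Exception):
    """Base class for all package errors."""


class ConfigError(SegtrendsError):
    """Invalid configuration or parameter values."""


class DatasetError(SegtrendsError):
    """Problems with input data."""


class SchemaError(DatasetError):
    """A required column is missing after applying the column mapping."""


class ValidationError(DatasetError):
    """One or more data rows violate the record invariants."""


class EmptySelectionError(DatasetError):
    """A grouping or filter left no usable groups."""


class SizeGuardError(ConfigError):
    """An exact-enumeration instance exceeds the size guard."""
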