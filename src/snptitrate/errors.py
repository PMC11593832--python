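"""Exception hierarchy shared across the package."""


class SnptitrateError(Exception):
    """Base class for package errors."""


class ConfigError(SnptitrateError):
    """Invalid configuration value; the message names the offending field."""


class DataError(SnptitrateError):
    """Inconsistent or malformed in-memory data (duplicate keys, missing labels)."""


class VCFFormatError(SnptitrateError):
    """Unreadable or malformed VCF input."""


class UndefinedMetricError(SnptitrateError):
    """A metric has no defined value on this input (e.g. empty denominator)."""
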