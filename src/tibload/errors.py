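"""Exception types raised across the package."""


class TibloadError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TibloadError):
    """A delimited-text file does not match the expected dialect."""


class ValidationError(TibloadError):
    """A domain object violates one of its invariants."""


class ParameterError(TibloadError):
    """An operation received an out-of-range parameter."""


class ConfigError(TibloadError):
    """A run configuration document is malformed or out of range."""


class IncompleteSeriesError(TibloadError):
    """A per-minute series has missing minutes where completeness is required."""
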