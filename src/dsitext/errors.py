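"""Exception hierarchy shared across the package."""


class DsitextError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DsitextError):
    """Raised when user-supplied data violates a precondition (empty text, bad columns, ...)."""


class InvalidParameterError(DsitextError):
    """Raised when a configuration value is outside its legal range."""


class FormatError(DsitextError):
    """Raised when an input file does not conform to its declared dialect."""


class ConfigurationError(DsitextError):
    """Raised when a backend is requested but its runtime requirements are missing."""


class UndefinedStatisticError(DsitextError):
    """Raised when a statistic is mathematically undefined for the given data."""
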