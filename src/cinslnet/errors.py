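"""Exception types shared across the pipeline."""


class CinSlNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CinSlNetError, ValueError):
    """A configuration value is outside its documented domain."""


class ConsistencyError(CinSlNetError, ValueError):
    """Inputs that must come from the same simulation/config disagree."""


class UndefinedValueError(CinSlNetError, ValueError):
    """A requested quantity is mathematically undefined for this input
    (empty gene list, zero denominator, ...)."""


class DomainError(CinSlNetError, ValueError):
    """A numeric argument lies outside the function's domain."""
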