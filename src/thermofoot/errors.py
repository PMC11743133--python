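"""Exception hierarchy shared across the package."""


class ThermofootError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ThermofootError, ValueError):
    """A numeric argument violates a documented precondition."""


class SchemaError(ThermofootError, ValueError):
    """A table or config file does not match its declared schema."""


class UndefinedStatisticError(ThermofootError, ValueError):
    """A statistic is undefined for the given (degenerate) input."""


class ConfigurationError(ThermofootError, ValueError):
    """Inconsistent or incomplete run configuration."""
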