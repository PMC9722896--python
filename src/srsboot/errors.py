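"""Exception hierarchy shared across the package."""


class SrsbootError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SrsbootError):
    """Invalid user-supplied configuration (frequencies, spacings, ...)."""


class DegenerateInputError(SrsbootError):
    """Input is structurally valid but degenerate (zero variance, ...)."""


class UndefinedMetricError(SrsbootError):
    """A metric cannot be computed, e.g. a single-class stratum."""


class InsufficientDataError(SrsbootError):
    """Not enough data to run the requested analysis."""


class SchemaError(SrsbootError):
    """A delimited-text table does not match the expected schema."""
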