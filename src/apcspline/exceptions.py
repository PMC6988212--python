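"""Exception hierarchy shared across the package."""


class APCError(Exception):
    """Base class for all apcspline errors."""


class ValidationError(APCError, ValueError):
    """Input data or argument violates a documented invariant."""


class ConfigurationError(APCError, ValueError):
    """Malformed configuration: missing columns, unknown options, bad files."""


class FittingError(APCError, RuntimeError):
    """Numerical failure while assembling or fitting a model."""
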