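"""Package-wide exception types."""


class KrillabError(Exception):
    """Base class for all package errors."""


class ParameterError(KrillabError, ValueError):
    """A model or configuration parameter is outside its valid domain."""


class InputError(KrillabError, ValueError):
    """User-supplied data violate a precondition (negative abundance, ...)."""


class IntegrationError(KrillabError, RuntimeError):
    """The ODE solver failed; carries the last time it reached."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class ConfigurationError(KrillabError, ValueError):
    """Inconsistent run configuration (overlapping windows, shape mismatch)."""
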