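"""Exception hierarchy for szdet."""


class SzdetError(Exception):
    """Base class for all szdet errors."""


class ValidationError(SzdetError, ValueError):
    """Input data violates a documented invariant."""


class ConfigurationError(SzdetError, ValueError):
    """A configuration value is inconsistent or out of range."""


class DesignError(SzdetError, RuntimeError):
    """A filter design cannot meet its specification.

    Carries the best attenuation actually achieved so callers can report
    how far the design fell short.
    """

    def __init__(self, message: str, achieved_atten_db: float | None = None):
        super().__init__(message)
        self.achieved_atten_db = achieved_atten_db


class UnsupportedFormatError(SzdetError, ValueError):
    """A file is structurally valid but uses an unsupported variant."""
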