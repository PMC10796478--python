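"""Exception hierarchy shared across the package."""


class GrazeratesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GrazeratesError, ValueError):
    """A delimited-text input is structurally malformed (e.g. missing column)."""


class ValidationError(GrazeratesError, ValueError):
    """A well-formed input violates a data-model invariant."""


class UndefinedRateError(GrazeratesError, ValueError):
    """A rate cannot be computed (zero/negative concentration at an endpoint)."""


class ConfigurationError(GrazeratesError, ValueError):
    """Inconsistent analysis configuration (e.g. grazed flask without a control)."""
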