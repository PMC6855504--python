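"""Exception types shared across the package."""


class OdColumnError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OdColumnError, ValueError):
    """A model or acquisition parameter is outside its valid range."""


class DomainError(OdColumnError, ValueError):
    """A spatial query falls outside the simulated cortical patch."""


class ConfigurationError(OdColumnError, ValueError):
    """A stimulus/map combination admits no valid source location."""


class GridMismatchError(OdColumnError, ValueError):
    """Two fields that must share a grid do not."""


class SingularFilterError(OdColumnError, ZeroDivisionError):
    """Inverse filtering requested where the transfer function vanishes."""


class DegenerateProfileError(OdColumnError, ValueError):
    """Profile extraction attempted on an all-zero or constant field."""
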