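"""Exception hierarchy shared across the package."""


class SwayBamError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SwayBamError, ValueError):
    """Input data violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A trial or manifest file could not be parsed; message names the line."""


class ConfigurationError(SwayBamError, ValueError):
    """A spec/config object is internally inconsistent or infeasible."""
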