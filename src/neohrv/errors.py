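"""Exception hierarchy shared across the package."""


class NeoHRVError(Exception):
    """Base class for all package-specific errors."""


class ParseError(NeoHRVError):
    """A data file could not be parsed; the message names the offending line."""


class ValidationError(NeoHRVError, ValueError):
    """An input violated a structural invariant."""


class QualityError(NeoHRVError):
    """A recording failed the automated quality screen."""


class InsufficientDataError(NeoHRVError):
    """Too few beats (or values) for the requested computation."""


class ParameterError(NeoHRVError, ValueError):
    """A parameter was outside its documented valid range."""
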