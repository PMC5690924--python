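"""Exception hierarchy for plan validation and evaluation failures."""


class SbrtqaError(Exception):
    """Base class for all package errors."""


class ValidationError(SbrtqaError):
    """Input violates a domain invariant (negative dose, empty mask, ...)."""


class GeometryError(SbrtqaError):
    """Frame-of-reference mismatch or degenerate spatial configuration."""


class FormatError(SbrtqaError):
    """Unreadable or malformed plan file."""


class NormalizationError(SbrtqaError):
    """Plan cannot be rescaled to the requested coverage."""
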