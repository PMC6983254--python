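"""Exception hierarchy for postucal.

All library errors derive from :class:`PostucalError` so callers (and the
CLI) can catch everything the pipeline may raise with one except clause.
"""


class PostucalError(Exception):
    """Base class for all postucal errors."""


class FormatError(PostucalError):
    """Input table does not have the expected column layout."""


class ParseError(PostucalError):
    """A cell could not be converted to a number."""


class SamplingError(PostucalError):
    """Timestamps are not uniformly sampled."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class ParameterError(PostucalError):
    """A parameter is outside its valid range."""


class LengthError(PostucalError):
    """The record is too short for the requested operation."""


class NoQuasiStaticError(PostucalError):
    """No quasi-static samples were found; gravity cannot be estimated."""


class DegenerateGravityError(PostucalError):
    """The mean quasi-static reading is too small to define a direction."""


class InsufficientMotionError(PostucalError):
    """Too few motion samples to recover a heading."""


class InvalidRotationError(PostucalError):
    """A supplied matrix is not a proper rotation."""


class AlignmentError(PostucalError):
    """Per-sample inputs do not have matching lengths."""


class ConfigError(PostucalError):
    """A scenario or run configuration is invalid."""


class IsotropicMotionWarning(UserWarning):
    """Horizontal motion is nearly isotropic; the heading is unreliable."""
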