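"""Exception hierarchy.

Every error raised deliberately by the package derives from
:class:`PlaquantError`, so callers can distinguish pipeline failures from
programming errors.
"""


class PlaquantError(Exception):
    """Base class for all errors raised by plaquant."""


class ValidationError(PlaquantError):
    """Inputs are structurally inconsistent (shape mismatch, bad manifest row)."""


class FormatError(PlaquantError):
    """A file is not in an accepted format (e.g. float or RGB TIFF)."""


class ParameterError(PlaquantError):
    """A parameter value is outside its admissible range."""


class GenerationError(PlaquantError):
    """Synthetic-scene construction failed (e.g. object packing failure)."""


class DegenerateImageError(PlaquantError):
    """An image is degenerate for the requested operation (e.g. constant plane)."""


class UndefinedRatioError(PlaquantError):
    """A ratio or percentage is undefined because its denominator is empty."""


class InsufficientDataError(PlaquantError):
    """Too few observations for the requested statistical procedure."""
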