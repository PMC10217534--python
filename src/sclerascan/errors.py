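"""Exception hierarchy.

Every error raised by the package derives from :class:`SclerascanError`
so callers (and the CLI) can map failures onto exit codes:

* input / I-O problems        -> :class:`InputError` (exit 2)
* degenerate segmentation     -> :class:`SegmentationError` (exit 3)
* bad configuration values    -> :class:`ConfigError` (exit 4)
"""


class SclerascanError(Exception):
    """Base class for all package errors."""


class InputError(SclerascanError):
    """Unreadable, malformed, or semantically invalid input."""


class ImageReadError(InputError):
    """File missing, truncated, or not a decodable raster image."""


class ImageFormatError(InputError):
    """Decodable, but not 8-bit RGB-like content."""


class DegenerateInputError(InputError):
    """Input technically valid but carries no usable signal (e.g. all-black)."""


class ParameterError(SclerascanError, ValueError):
    """A function argument violates its contract."""


class SegmentationError(SclerascanError):
    """Eye-region extraction failed."""


class DegenerateRoiError(SegmentationError):
    """Too few measurable pixels survive in a region of interest."""


class NoEyesFoundError(SegmentationError):
    """No ROI could be obtained for any input image."""


class InfeasibleSceneError(SclerascanError):
    """A synthetic scene specification cannot be rendered (e.g. occluders
    covering nearly the whole sclera)."""


class DegenerateCohortError(SclerascanError):
    """Cohort statistics requested on a single-class or constant cohort."""


class UndefinedCorrelationError(DegenerateCohortError):
    """Rank correlation of a constant vector is undefined."""


class ConfigError(SclerascanError):
    """Invalid configuration file or value."""
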