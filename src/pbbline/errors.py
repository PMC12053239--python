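"""Exception hierarchy shared across the package."""


class PbblineError(Exception):
    """Base class for all package-specific errors."""


class InvalidPolygonError(PbblineError, ValueError):
    """A polygon violates its structural requirements (too few vertices,
    self-intersection, non-finite coordinates)."""


class ParameterError(PbblineError, ValueError):
    """A numeric parameter is outside its admissible range."""


class NoRoIError(PbblineError, RuntimeError):
    """Region-of-interest extraction found no foreground after thresholding
    and morphological refinement."""


class DegenerateImageError(PbblineError, ValueError):
    """An image does not carry enough intensity variation for the requested
    operation (e.g. Otsu thresholding of a constant image)."""


class LabelFormatError(PbblineError, ValueError):
    """An annotation or label file is malformed."""


class TextDetectionError(PbblineError, RuntimeError):
    """A pluggable text detector failed."""
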