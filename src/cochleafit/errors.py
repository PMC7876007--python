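"""Exception types shared across the fitting pipeline."""


class CochleaFitError(Exception):
    """Base class for all package errors."""


class ParameterError(CochleaFitError, ValueError):
    """A geometric or configuration parameter is invalid."""


class EmptyCloudError(CochleaFitError, ValueError):
    """Segmentation produced no boundary points."""


class DegenerateLandmarksError(CochleaFitError, ValueError):
    """Landmark triad is collinear or otherwise unusable."""


class CorrespondenceError(CochleaFitError, ValueError):
    """Vertex sets do not share the template topology."""


class TracingError(CochleaFitError, RuntimeError):
    """Outer-wall contour tracing failed."""


class FormatError(CochleaFitError, ValueError):
    """An on-disk artifact is malformed or unsupported."""


class SchemaError(FormatError):
    """A JSON artifact is missing required fields."""
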