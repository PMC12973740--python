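"""Exception hierarchy.

Every error raised by this package derives from :class:`MandifracError`,
so callers can catch the whole family while still seeing standard Python
categories (``ValueError``, ``RuntimeError``, ...) via multiple inheritance.
"""


class MandifracError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MandifracError, ValueError):
    """A parameter is outside its documented domain."""


class RoiBoundsError(MandifracError, IndexError):
    """A region of interest extends beyond the source image."""


class DimensionError(MandifracError, ValueError):
    """Two grids that must share a shape do not."""


class PipelineOrderError(MandifracError, RuntimeError):
    """A preprocessing stage was invoked on a patch in the wrong stage."""


class DegenerateInputError(MandifracError, ValueError):
    """The input carries no analysable signal (e.g. empty foreground)."""


class InsufficientScalesError(MandifracError, ValueError):
    """Fewer than three box sizes available for the log-log regression."""


class GeometryError(MandifracError, ValueError):
    """Landmark geometry is degenerate (repeated points, zero height...)."""


class MeasurementError(GeometryError):
    """A morphometric measurement could not be completed on the landmarks."""


class InsufficientDataError(MandifracError, ValueError):
    """A statistical routine received fewer observations than it requires."""


class CollinearityError(MandifracError, ValueError):
    """The regression design matrix is rank deficient."""


class SchemaError(MandifracError, ValueError):
    """A table violates the expected schema; message names column/line."""
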