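"""Exception hierarchy.

Two broad families matter to callers (and set the CLI exit code):
:class:`InputError` for malformed or inconsistent user input, and
:class:`DegenerateDataError` for inputs that are well-formed but carry no
usable signal (constant histograms, zero-variance regressors, ...).
"""


class TongueGlossError(Exception):
    """Base class for all package errors."""


class InputError(TongueGlossError, ValueError):
    """Malformed, missing or mutually inconsistent input."""


class DegenerateDataError(TongueGlossError, ValueError):
    """Well-formed input from which the requested quantity is undefined."""


class ShapeMismatchError(InputError):
    """Arrays that must share a shape do not."""


class InsufficientPatchesError(InputError):
    """Too few colour-chart patches for the requested regression."""


class CalibrationDegenerateError(DegenerateDataError):
    """Chart RGBs do not span the regression design space."""


class EmptyRoiError(InputError):
    """A region-of-interest mask selects no pixels."""


class EmptyMaskError(InputError):
    """A tongue/ROI mask file contains no foreground pixels."""


class RoiOutOfBoundsError(InputError):
    """The constructed ROI square leaves the image."""


class DegenerateHistogramError(DegenerateDataError):
    """Otsu thresholding of a (near-)constant value collection."""
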