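"""Exception hierarchy.

Everything derives from :class:`CtiqError` so callers can catch the package's
failures in one clause; most are also ``ValueError`` subclasses because they
signal invalid inputs.
"""


class CtiqError(Exception):
    """Base class for all ctiq errors."""


class GeometryError(CtiqError, ValueError):
    """Phantom geometry is inconsistent (insert outside image, bad spacing...)."""


class ParameterError(CtiqError, ValueError):
    """A model parameter is out of its valid range (e.g. noise peak >= Nyquist)."""


class LayoutError(CtiqError, ValueError):
    """An ROI layout violates image bounds or overlaps the insert."""


class InputError(CtiqError, ValueError):
    """Malformed input to an estimator (mixed patch sizes, empty battery...)."""


class DetectionError(CtiqError, RuntimeError):
    """The insert could not be located in the image."""


class InsufficientDataError(CtiqError, RuntimeError):
    """Too few samples to form a reliable estimate (sparse ESF bins)."""


class UndefinedPeakError(CtiqError, RuntimeError):
    """Peak frequency requested of an all-zero spectrum."""


class OutOfRangeError(CtiqError, RuntimeError):
    """A level crossing was requested outside the curve's range."""


class QualityWarning(UserWarning):
    """Non-fatal data-quality issue (baseline trend, clipped NPS values)."""
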