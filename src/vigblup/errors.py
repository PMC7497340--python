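"""Exception hierarchy shared across the package.

All user-facing errors derive from :class:`VigblupError` so callers can catch
one base class at pipeline boundaries.
"""


class VigblupError(Exception):
    """Base class for all package errors."""


class ParameterError(VigblupError, ValueError):
    """An argument is outside its documented domain."""


class SchemaError(VigblupError, ValueError):
    """An input table violates the documented schema."""


class FormatError(VigblupError, ValueError):
    """A file could not be parsed as the declared format."""


class UndefinedValueError(VigblupError, ArithmeticError):
    """A formula is undefined for the given inputs (e.g. zero denominator)."""


class PedigreeError(VigblupError, KeyError):
    """A hybrid references a parent missing from the relationship matrices."""


class CoverageError(VigblupError, ValueError):
    """A weather table does not cover the requested date span."""


class ExtrapolationError(VigblupError, ValueError):
    """A time point lies outside the spline knot range; no extrapolation."""


class IdentifiabilityError(VigblupError, ValueError):
    """The requested model is not identifiable from the data provided."""


class LinearAlgebraError(VigblupError, ArithmeticError):
    """A matrix does not satisfy a required property (e.g. positive definite)."""
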