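"""Exception hierarchy.

All package-specific failures derive from :class:`FxrSpecError` so callers can
catch one base class; the subclasses distinguish I/O schema problems from
domain-validation and fitting failures.
"""


class FxrSpecError(Exception):
    """Base class for all package errors."""


class SchemaError(FxrSpecError):
    """A delimited file does not match the documented column schema."""


class ParseError(FxrSpecError):
    """A cell or record could not be parsed as a number."""


class ValidationError(FxrSpecError):
    """A domain object violates one of its invariants."""


class GridMismatchError(ValidationError):
    """Two spectra do not share an identical wavelength grid."""


class UnitsError(ValidationError):
    """An operation received data in the wrong units."""


class FitError(FxrSpecError):
    """A regression could not be performed on the given data."""
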