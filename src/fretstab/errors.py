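"""Exception hierarchy shared across analysis stages."""


class FretstabError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FretstabError):
    """A precondition on the input data is violated."""


class DomainError(FretstabError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class SchemaError(InvalidInputError):
    """An input file is missing a required column or has a bad header."""


class ParseError(InvalidInputError):
    """A cell in an input file cannot be parsed; carries the row number."""


class MissingControlError(InvalidInputError):
    """A required control well / control series entry is absent."""


class DegenerateControlError(InvalidInputError):
    """A control well has a non-positive denominator channel."""


class DegenerateDataError(FretstabError):
    """The data carry no signal the requested fit could use."""


class DegenerateCurveError(DegenerateDataError):
    """A curve is constant where variation is required."""


class InsufficientDataError(FretstabError):
    """Too few points satisfy the fit's selection criteria."""


class FitFailureError(FretstabError):
    """A nonlinear fit did not converge.

    Attributes
    ----------
    p0 : sequence or None
        Initial parameter values used.
    details : str
        Optimizer diagnostics.
    """

    def __init__(self, message, p0=None, details=""):
        super().__init__(message)
        self.p0 = p0
        self.details = details


class EstimationFailureError(FretstabError):
    """A free-energy estimator could not produce a finite answer."""
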