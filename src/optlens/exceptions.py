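"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`OptLensError`
so callers can catch analysis failures without masking programming errors.
"""


class OptLensError(Exception):
    """Base class for all errors raised by optlens."""


class DomainError(OptLensError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateInputError(DomainError):
    """Input is formally admissible but leaves the quantity unidentifiable
    (e.g. a zero proliferation index when estimating the pull-through rate)."""


class UnsupportedRegionError(OptLensError):
    """Model evaluation requested beyond the region the parameter set covers
    (past the density peak when no decline scale delta is defined)."""


class IntegrationError(OptLensError):
    """The numerical ODE oracle failed to reach the requested accuracy."""


class InsufficientDataError(OptLensError):
    """Too few samples to carry out an estimation step."""


class FlatProfileError(OptLensError):
    """The profile never rises above its plateau; the two-line construction
    and the plateau-edge search are undefined."""


class GeometryError(OptLensError):
    """The two-line intercept construction failed (no bracketed mid-level
    crossing, or the flank tangent does not intersect the baseline)."""


class UnidentifiableError(OptLensError):
    """The requested free parameters cannot be constrained by the data
    (e.g. no points beyond the plateau edge)."""


class ConvergenceError(OptLensError):
    """An optimiser failed to converge and strict mode is on."""


class OutOfValidityError(OptLensError):
    """An ageing-model evaluation outside the range where the fitted
    relation stays positive/meaningful."""


class ValidationError(OptLensError):
    """A data file failed schema or consistency validation.

    ``rows`` carries the offending 1-based data-row numbers (header excluded)
    and ``messages`` a human-readable description per problem.
    """

    def __init__(self, messages, rows=None):
        self.messages = list(messages)
        self.rows = list(rows) if rows is not None else []
        super().__init__("; ".join(self.messages))
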