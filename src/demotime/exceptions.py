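"""Exception hierarchy for demotime.

All library errors derive from :class:`DemotimeError` so callers can catch
one base class; argument errors additionally derive from the built-in
``ValueError`` so sloppy call sites fail in the conventional way.
"""


class DemotimeError(Exception):
    """Base class for all demotime errors."""


class InvalidArgumentError(DemotimeError, ValueError):
    """An argument is outside its documented domain."""


class InconsistencyError(DemotimeError, ValueError):
    """Supplied time measures contradict one of the identity equations."""

    def __init__(self, identity: str, residual: float, message: str | None = None):
        self.identity = identity
        self.residual = residual
        super().__init__(
            message
            or f"identity {identity} violated (residual {residual:g} years)"
        )


class DomainViolationError(DemotimeError, ValueError):
    """A derived duration (age, time to death, lifespan) came out negative."""


class MissingMeasureError(DemotimeError, KeyError):
    """A required time measure is absent from a coordinate."""


class OutOfRangeError(DemotimeError, ValueError):
    """An observation time falls outside the lifeline's [birth, death] span."""


class CensoringError(DemotimeError, ValueError):
    """A death-anchored quantity was requested for a censored lifeline."""


class UndefinedStatisticError(DemotimeError, ValueError):
    """A summary statistic is undefined on a degenerate input."""


class UndefinedExpectancyError(DemotimeError, ZeroDivisionError):
    """No survivors at the requested starting age."""


class FormatError(DemotimeError, ValueError):
    """An input file does not conform to the documented layout."""
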