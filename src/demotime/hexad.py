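"""The six demographic time measures and their joint identity.

Measures (all in years, calendar measures as decimal calendar years):

===  ========================  ==========================
A    chronological age         time since birth
P    period                    calendar time of observation
C    birth cohort              calendar time of birth
T    thanatological age        time remaining until death
D    death cohort              calendar time of death
L    lifespan                  total length of life
===  ========================  ==========================

They are linked by four triad identities — any two members of a triad
determine the third::

    APC:  A = P - C        TPD:  T = D - P
    TAL:  L = A + T        LCD:  L = D - C

Knowing any informative dyad plus one further independent measure pins
down all six.  Three dyads (LP, CT, AD) are uninformative: their edges
share no triangle in the measure graph, so nothing new follows from them.

Unlike the general event-duration machinery in :mod:`demotime.events`,
this module enforces demographic semantics: A, T and L must be
non-negative and the events must be ordered C <= P <= D.

Dates given only to calendar-year precision follow a completed-year
convention: a birth "in year y" is the instant y.0, while an event known
only to *close* an interval in year y (a death reported as "December
1995" with a completed lifespan) is carried at the following year
boundary, y+1.  Completed-year inputs therefore carry up to one year of
ambiguity, which is not modelled further.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional

from .exceptions import (
    CensoringError,
    DomainViolationError,
    InconsistencyError,
    InvalidArgumentError,
    OutOfRangeError,
)

__all__ = [
    "MEASURES",
    "IDENTITIES",
    "DemographicCoordinate",
    "Lifeline",
    "Observation",
    "complete",
    "derivable_set",
    "check_consistency",
    "measures_at",
]

#: Canonical measure order.
MEASURES = ("A", "P", "C", "T", "D", "L")

#: The four triad identities as (name, (x, y, z)) with x = y - z.
#: APC: A = P - C;  TPD: T = D - P;  TAL: T = L - A;  LCD: L = D - C.
IDENTITIES: dict[str, tuple[str, str, str]] = {
    "APC": ("A", "P", "C"),
    "TPD": ("T", "D", "P"),
    "TAL": ("T", "L", "A"),
    "LCD": ("L", "D", "C"),
}

#: Measures that are durations and must be non-negative.
DURATION_MEASURES = frozenset({"A", "T", "L"})

DEFAULT_EPS = 1e-9


@dataclass(frozen=True)
class DemographicCoordinate:
    """A partial or complete (A, P, C, T, D, L) tuple.

    Unknown measures are ``None``.  Construction does not validate the
    identities; use :func:`complete` or :func:`check_consistency`.
    """

    A: Optional[float] = None
    P: Optional[float] = None
    C: Optional[float] = None
    T: Optional[float] = None
    D: Optional[float] = None
    L: Optional[float] = None

    def get(self, measure: str) -> Optional[float]:
        if measure not in MEASURES:
            raise InvalidArgumentError(f"unknown measure {measure!r}")
        return getattr(self, measure)

    def replace(self, **kwargs: Optional[float]) -> "DemographicCoordinate":
        return dataclasses.replace(self, **kwargs)

    def present(self) -> set[str]:
        """Labels of the measures that are set."""
        return {m for m in MEASURES if self.get(m) is not None}

    def as_dict(self) -> dict[str, float]:
        return {m: self.get(m) for m in MEASURES if self.get(m) is not None}

    def is_complete(self) -> bool:
        return len(self.present()) == 6

    def __repr__(self) -> str:  # compact: only the set fields
        inner = ", ".join(f"{m}={self.get(m):g}" for m in MEASURES if self.get(m) is not None)
        return f"DemographicCoordinate({inner})"


@dataclass(frozen=True)
class Lifeline:
    """An individual's birth and (possibly censored) death time.

    ``death=None`` marks right censoring: the individual was alive at the
    end of follow-up, so T, D and L are unknowable, not zero.
    """

    id: object
    birth: float
    death: Optional[float] = None

    def __post_init__(self):
        if self.death is not None and self.death < self.birth:
            raise InvalidArgumentError(
                f"lifeline {self.id!r}: death {self.death} precedes birth {self.birth}"
            )

    @property
    def censored(self) -> bool:
        return self.death is None

    @property
    def lifespan(self) -> Optional[float]:
        return None if self.death is None else self.death - self.birth


@dataclass(frozen=True)
class Observation:
    """One dated measurement on a lifeline (panel interview, reading...)."""

    id: object
    time: float
    value: Optional[float] = None
    weight: float = 1.0


def _validate_labels(labels: Iterable[str]) -> set[str]:
    labels = set(labels)
    unknown = labels - set(MEASURES)
    if unknown:
        raise InvalidArgumentError(f"unknown measure labels {sorted(unknown)}")
    return labels


def derivable_set(given: Iterable[str]) -> set[str]:
    """Measures derivable (but not already given) from a set of labels.

    Transitive closure under the four identities: while any identity has
    exactly two of its three members, the third joins the closure.  The
    uninformative dyads {L,P}, {C,T}, {A,D} yield nothing; neither does a
    full triad on its own (e.g. T, A, L gives no calendar anchor).
    """
    given = _validate_labels(given)
    closure = set(given)
    changed = True
    while changed:
        changed = False
        for _, members in IDENTITIES.items():
            have = [m for m in members if m in closure]
            if len(have) == 2:
                missing = next(m for m in members if m not in closure)
                closure.add(missing)
                changed = True
    return closure - given


def complete(
    coord: DemographicCoordinate, eps: float = DEFAULT_EPS
) -> DemographicCoordinate:
    """Fill in every measure derivable from the given ones.

    Applies the four identity equations to a fixpoint.  Idempotent and
    order-independent: the derived values are unique whenever they are
    derivable at all.  Raises :class:`InconsistencyError` if the supplied
    measures contradict an identity by more than ``eps`` years, and
    :class:`DomainViolationError` if a derived duration (A, T or L) is
    negative beyond ``eps``.
    """
    if eps <= 0:
        raise InvalidArgumentError(f"eps must be positive, got {eps}")
    values: dict[str, float] = coord.as_dict()
    derived: set[str] = set()
    # Four identities, <=3 new values each pass: 6 passes always suffice.
    for _ in range(8):
        changed = False
        for name, (x, y, z) in IDENTITIES.items():
            have = {m: values[m] for m in (x, y, z) if m in values}
            if len(have) == 3:
                residual = abs(values[y] - values[z] - values[x])
                if residual > eps:
                    raise InconsistencyError(name, residual)
                continue
            if len(have) != 2:
                continue
            if x not in values:
                values[x] = values[y] - values[z]
                derived.add(x)
            elif y not in values:
                values[y] = values[x] + values[z]
                derived.add(y)
            else:
                values[z] = values[y] - values[x]
                derived.add(z)
            changed = True
        if not changed:
            break
    for m in derived & DURATION_MEASURES:
        if values[m] < -eps:
            raise DomainViolationError(
                f"derived {m} = {values[m]:g} is negative; "
                "check the ordering C <= P <= D of the inputs"
            )
        if values[m] < 0.0:  # tolerated rounding noise
            values[m] = 0.0
    return DemographicCoordinate(**values)


def check_consistency(
    coord: DemographicCoordinate, eps: float = DEFAULT_EPS
) -> list[str]:
    """List identity/ordering violations; empty means consistent.

    Checks each identity whose three members are all present (residual
    must not exceed ``eps``), non-negativity of present durations, and the
    event ordering C <= P <= D for present pairs.  Violations are returned,
    not raised.
    """
    if eps <= 0:
        raise InvalidArgumentError(f"eps must be positive, got {eps}")
    violations: list[str] = []
    values = coord.as_dict()
    for name, (x, y, z) in IDENTITIES.items():
        if all(m in values for m in (x, y, z)):
            residual = abs(values[y] - values[z] - values[x])
            if residual > eps:
                violations.append(
                    f"{name}: {x} != {y} - {z} (residual {residual:g} years)"
                )
    for m in sorted(DURATION_MEASURES):
        if m in values and values[m] < -eps:
            violations.append(f"{m} = {values[m]:g} is negative")
    for lo, hi in (("C", "P"), ("P", "D"), ("C", "D")):
        if lo in values and hi in values and values[lo] - values[hi] > eps:
            violations.append(
                f"event ordering violated: {lo} = {values[lo]:g} > {hi} = {values[hi]:g}"
            )
    return violations


def measures_at(
    lifeline: Lifeline, P: float, eps: float = DEFAULT_EPS
) -> DemographicCoordinate:
    """All measures of a lifeline at observation time ``P``.

    Uncensored lifelines yield all six measures; censored ones only the
    birth-anchored A, P, C (T, D, L stay unset rather than guessed).
    ``P`` must lie within [birth, death].
    """
    if P < lifeline.birth - eps:
        raise OutOfRangeError(
            f"observation time {P} precedes birth {lifeline.birth} "
            f"of lifeline {lifeline.id!r}"
        )
    if lifeline.death is not None and P > lifeline.death + eps:
        raise OutOfRangeError(
            f"observation time {P} exceeds death {lifeline.death} "
            f"of lifeline {lifeline.id!r}"
        )
    base = DemographicCoordinate(P=P, C=lifeline.birth, D=lifeline.death)
    return complete(base, eps=eps)


def lifeline_coordinate(lifeline: Lifeline) -> DemographicCoordinate:
    """The time-invariant (C, D, L) coordinate of an uncensored lifeline."""
    if lifeline.censored:
        raise CensoringError(
            f"lifeline {lifeline.id!r} is censored; C/D/L are unknown"
        )
    return complete(DemographicCoordinate(C=lifeline.birth, D=lifeline.death))
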