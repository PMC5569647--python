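"""Lifetables and prevalence-based health expectancies.

Two routes from a lifetable plus a morbidity-prevalence schedule to
healthy (HLE) and unhealthy (UHLE) life expectancy:

* **Sullivan method** — prevalence by chronological age ``pi(a)``
  weights the lifetable person-years:
  ``UHLE(x0) = sum_{a>=x0} Lx(a) * pi(a) / l(x0)``.
* **Time-to-death method** — prevalence by thanatological age ``g(t)``
  weights each death by the unhealthy years lived before it:
  ``UHLE(x0) = sum_{a>=x0} [d(a)/l(x0)] * G(a - x0)`` with
  ``G(k) = sum_{t<k} g(t) + g(k)/2``.

Both satisfy HLE + UHLE = e(x0) exactly.  Discrete conventions are fixed
package-wide: deaths at interval midpoints, ``Lx = l(x+1) + d(x)/2``, and
the half-interval term in ``G``.  Under these conventions a constant
prevalence ``g = p`` gives ``UHLE = p * e(x0)`` in closed form for both
methods — the behaviour the time-to-death model logically requires: if
morbidity is purely a function of time to death, added longevity is added
healthy time.

:func:`implied_age_prevalence` gives the chronological-age prevalence
that a fixed time-to-death trajectory induces in a stationary population
(the death-time mixture ``pi(a) = sum_t [d(a+t)/l(a)] g(t)``), and
:func:`compare_scenarios` contrasts projecting morbidity with a frozen
Sullivan curve against the time-to-death model when mortality changes —
the frozen curve overstates growth in unhealthy years whenever
prevalence concentrates near death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedExpectancyError

__all__ = [
    "Lifetable",
    "TTDPrevalence",
    "AgePrevalence",
    "build_lifetable",
    "sullivan",
    "ttd_expectancies",
    "implied_age_prevalence",
    "compare_scenarios",
    "ScenarioReport",
    "DEFAULT_OMEGA",
]

log = logging.getLogger(__name__)

DEFAULT_OMEGA = 110


@dataclass(frozen=True)
class Lifetable:
    """A single-year-of-age period lifetable on an integer grid 0..omega.

    ``l`` survivors at exact age x (radix-scaled), ``d`` deaths in
    [x, x+1), ``L`` person-years lived in [x, x+1) under the midpoint
    convention ``L(x) = l(x+1) + d(x)/2``, and ``e`` remaining life
    expectancy.  The last age group is closed out: q(omega) = 1.
    """

    x: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        for name in ("x", "l", "d", "L", "e"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "x", self.x.astype(int))
        n = self.x.size
        if any(getattr(self, name).size != n for name in ("l", "d", "L", "e")):
            raise InvalidArgumentError("lifetable columns must share one age grid")

    @property
    def omega(self) -> int:
        return int(self.x[-1])

    @property
    def radix(self) -> float:
        return float(self.l[0])

    def expectancy(self, x0: int) -> float:
        """Remaining life expectancy at integer age ``x0``."""
        i = self._index(x0)
        return float(self.e[i])

    def _index(self, x0: int) -> int:
        if not (self.x[0] <= x0 <= self.omega):
            raise InvalidArgumentError(f"age {x0} outside grid {self.x[0]}..{self.omega}")
        i = int(x0 - self.x[0])
        if self.l[i] <= 0:
            raise UndefinedExpectancyError(f"no survivors at age {x0}")
        return i


def build_lifetable(
    qx: Sequence[float] | None = None,
    hazard: Sequence[float] | None = None,
    radix: float = 1.0,
    omega: int | None = None,
) -> Lifetable:
    """Construct an internally consistent lifetable from q(x) or hazards.

    Exactly one of ``qx`` (death probabilities in [0, 1]) or ``hazard``
    (non-negative, piecewise-constant within single-year intervals, so
    q = 1 - exp(-hazard)) must be given, on ages 0..omega.  The schedule
    is truncated or its last entry replaced so that q(omega) = 1 — the
    open-ended group is closed out at omega (default 110).
    """
    if (qx is None) == (hazard is None):
        raise InvalidArgumentError("give exactly one of qx= or hazard=")
    if hazard is not None:
        hazard = np.asarray(hazard, dtype=float)
        if hazard.ndim != 1 or hazard.size == 0 or np.any(hazard < 0) or not np.all(np.isfinite(hazard)):
            raise InvalidArgumentError("hazard must be a 1-d array of finite values >= 0")
        q = 1.0 - np.exp(-hazard)
    else:
        q = np.asarray(qx, dtype=float).copy()
        if q.ndim != 1 or q.size == 0 or np.any((q < 0) | (q > 1)) or not np.all(np.isfinite(q)):
            raise InvalidArgumentError("qx must be a 1-d array of probabilities in [0, 1]")
    if radix <= 0:
        raise InvalidArgumentError(f"radix must be positive, got {radix}")
    if omega is not None:
        if omega < 0:
            raise InvalidArgumentError(f"omega must be >= 0, got {omega}")
        if q.size > omega + 1:
            q = q[: omega + 1]
        elif q.size < omega + 1:
            q = np.append(q, np.full(omega + 1 - q.size, q[-1]))
    q[-1] = 1.0

    n = q.size
    l = np.empty(n)
    l[0] = radix
    l[1:] = radix * np.cumprod(1.0 - q[:-1])
    d = l * q
    l_next = np.append(l[1:], 0.0)
    L = l_next + d / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, np.cumsum(L[::-1])[::-1] / np.where(l > 0, l, 1.0), 0.0)
    return Lifetable(x=np.arange(n), l=l, d=d, L=L, e=e)


def _extend(values: np.ndarray, length: int, what: str) -> np.ndarray:
    """Pad a prevalence schedule with its final value (logged once per call)."""
    if values.size >= length:
        return values[:length]
    log.warning(
        "%s schedule shorter than needed (%d < %d); extending with final value %g",
        what,
        values.size,
        length,
        values[-1],
    )
    return np.append(values, np.full(length - values.size, values[-1]))


@dataclass(frozen=True)
class TTDPrevalence:
    """Prevalence by completed thanatological age t = 0, 1, 2, ...

    Values in [0, 1]; g(0) is the last year of life.  Beyond the supplied
    range the schedule is extended as its final value.
    """

    g: np.ndarray

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.g, dtype=float))
        if g.size == 0 or np.any((g < 0) | (g > 1)) or not np.all(np.isfinite(g)):
            raise InvalidArgumentError("prevalence values must lie in [0, 1]")
        object.__setattr__(self, "g", g)

    def values_to(self, length: int) -> np.ndarray:
        return _extend(self.g, length, "time-to-death prevalence")


@dataclass(frozen=True)
class AgePrevalence:
    """Prevalence by completed chronological age, starting at ``age0``."""

    pi: np.ndarray
    age0: int = 0

    def __post_init__(self):
        pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if pi.size == 0 or np.any((pi < 0) | (pi > 1)) or not np.all(np.isfinite(pi)):
            raise InvalidArgumentError("prevalence values must lie in [0, 1]")
        object.__setattr__(self, "pi", pi)

    def on_grid(self, x0: int, omega: int) -> np.ndarray:
        """Values on ages x0..omega; must cover the range below the top."""
        if x0 < self.age0:
            raise InvalidArgumentError(
                f"prevalence starts at age {self.age0}, cannot evaluate from {x0}"
            )
        idx = x0 - self.age0
        vals = self.pi[idx:] if idx < self.pi.size else self.pi[-1:]
        return _extend(vals, omega - x0 + 1, "age prevalence")


def sullivan(
    lifetable: Lifetable, pi: AgePrevalence, x0: int = 0
) -> tuple[float, float]:
    """Sullivan-method (HLE, UHLE) at age ``x0``.

    Unhealthy expectancy is the prevalence-weighted person-year sum
    ``sum_{a>=x0} Lx(a) pi(a) / l(x0)``; HLE is the remainder of e(x0).
    """
    i = lifetable._index(x0)
    pvals = pi.on_grid(x0, lifetable.omega)
    uhle = float(lifetable.L[i:] @ pvals) / lifetable.l[i]
    return lifetable.e[i] - uhle, uhle


def _unhealthy_years_before_death(g: np.ndarray) -> np.ndarray:
    """G(k): unhealthy years lived from the origin age to a death in interval k.

    A death in age interval ``x0 + k`` occurs at its midpoint, so the
    individual spends a full year at each completed thanatological age
    t < k and half a year at t = k: G(k) = sum_{t<k} g(t) + g(k)/2.
    """
    csum = np.concatenate([[0.0], np.cumsum(g[:-1])])
    return csum + g / 2.0


def ttd_expectancies(
    lifetable: Lifetable, g: TTDPrevalence, x0: int = 0
) -> tuple[float, float]:
    """Time-to-death-method (HLE, UHLE) at age ``x0``.

    Each death at age a >= x0 contributes G(a - x0) unhealthy years
    (see :func:`_unhealthy_years_before_death`), weighted by its share
    d(a)/l(x0) of the survivors at x0.
    """
    i = lifetable._index(x0)
    k = lifetable.omega - x0 + 1
    gvals = g.values_to(k)
    G = _unhealthy_years_before_death(gvals)
    uhle = float(lifetable.d[i:] @ G) / lifetable.l[i]
    return lifetable.e[i] - uhle, uhle


def implied_age_prevalence(lifetable: Lifetable, g: TTDPrevalence) -> AgePrevalence:
    """Chronological-age prevalence implied by a fixed time-to-death pattern.

    In the stationary population of the lifetable, survivors at exact age
    ``a`` are a mixture over their eventual completed time to death t,
    with weights d(a+t)/l(a), so ``pi(a) = sum_t [d(a+t)/l(a)] g(t)``.
    Defined up to the last age with survivors (truncated beyond).  This is
    the "Sullivan curve" a fixed thanatological pattern would print: when
    g falls with distance from death, longer-lived populations show lower
    prevalence at any fixed age.
    """
    alive = lifetable.l > 0
    last = int(np.max(np.nonzero(alive)))
    gvals = g.values_to(lifetable.omega + 1)
    pi = np.empty(last + 1)
    for a in range(last + 1):
        tail = lifetable.d[a:]
        pi[a] = float(tail @ gvals[: tail.size]) / lifetable.l[a]
    # mixtures of values in [0, 1]; clip float dust
    return AgePrevalence(np.clip(pi, 0.0, 1.0), age0=int(lifetable.x[0]))


@dataclass(frozen=True)
class ScenarioReport:
    """Mortality-change comparison of the two projection methods at one age.

    ``*_ttd`` fields apply the fixed time-to-death trajectory to each
    lifetable; ``*_fixed`` fields apply the frozen baseline Sullivan
    curve (the age prevalence implied by g under *baseline* mortality) to
    both lifetables — the standard practice the time-to-death model
    argues against.
    """

    x0: int
    e_base: float
    e_new: float
    uhle_base_ttd: float
    uhle_new_ttd: float
    uhle_base_fixed: float
    uhle_new_fixed: float

    @property
    def d_le(self) -> float:
        return self.e_new - self.e_base

    @property
    def d_uhle_ttd(self) -> float:
        return self.uhle_new_ttd - self.uhle_base_ttd

    @property
    def d_uhle_fixed(self) -> float:
        return self.uhle_new_fixed - self.uhle_base_fixed

    @property
    def d_hle_ttd(self) -> float:
        return self.d_le - self.d_uhle_ttd

    @property
    def d_hle_fixed(self) -> float:
        return self.d_le - self.d_uhle_fixed

    def pct_uhle_change(self, method: str) -> float:
        """Percent change of UHLE from base to new under a method."""
        if method == "ttd":
            base, delta = self.uhle_base_ttd, self.d_uhle_ttd
        elif method == "fixed":
            base, delta = self.uhle_base_fixed, self.d_uhle_fixed
        else:
            raise InvalidArgumentError("method must be 'ttd' or 'fixed'")
        if base == 0:
            return float("nan")
        return 100.0 * delta / base

    def as_dict(self) -> dict[str, float]:
        return {
            "x0": self.x0,
            "e_base": self.e_base,
            "e_new": self.e_new,
            "d_le": self.d_le,
            "uhle_base_ttd": self.uhle_base_ttd,
            "uhle_new_ttd": self.uhle_new_ttd,
            "d_uhle_ttd": self.d_uhle_ttd,
            "d_hle_ttd": self.d_hle_ttd,
            "uhle_base_fixed": self.uhle_base_fixed,
            "uhle_new_fixed": self.uhle_new_fixed,
            "d_uhle_fixed": self.d_uhle_fixed,
            "d_hle_fixed": self.d_hle_fixed,
        }


def compare_scenarios(
    lifetable_base: Lifetable,
    lifetable_new: Lifetable,
    g: TTDPrevalence,
    x0: int = 0,
) -> ScenarioReport:
    """Contrast time-to-death vs frozen-Sullivan morbidity projection.

    Computes UHLE at ``x0`` under both lifetables by (i) applying ``g``
    directly and (ii) applying the baseline lifetable's implied age
    prevalence to both — as if the baseline Sullivan curve were assumed
    to persist.  When mortality improves and g falls with time to death,
    route (ii) projects a larger rise in unhealthy years than route (i).
    """
    if lifetable_base.x.size != lifetable_new.x.size or np.any(
        lifetable_base.x != lifetable_new.x
    ):
        raise InvalidArgumentError("lifetables must share one age grid")
    _, uhle_base_ttd = ttd_expectancies(lifetable_base, g, x0)
    _, uhle_new_ttd = ttd_expectancies(lifetable_new, g, x0)
    pi_fixed = implied_age_prevalence(lifetable_base, g)
    _, uhle_base_fixed = sullivan(lifetable_base, pi_fixed, x0)
    _, uhle_new_fixed = sullivan(lifetable_new, pi_fixed, x0)
    return ScenarioReport(
        x0=x0,
        e_base=lifetable_base.expectancy(x0),
        e_new=lifetable_new.expectancy(x0),
        uhle_base_ttd=uhle_base_ttd,
        uhle_new_ttd=uhle_new_ttd,
        uhle_base_fixed=uhle_base_fixed,
        uhle_new_fixed=uhle_new_fixed,
    )
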