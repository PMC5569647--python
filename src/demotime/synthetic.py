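"""Synthetic lifelines, panels, lifetables and prevalence schedules.

The generator emulates the structure of a mortality follow-up panel
survey: a cohort of individuals with known birth times, Gompertz(-Makeham)
mortality, interviewed at regular waves, each interview recording a
binary morbidity indicator whose probability is a logistic function of
*time to death* — high in the last years of life and falling with
distance from death.  Ground truth (the hazard and the prevalence
trajectory) is known exactly, so every downstream estimate has an
analytic target.

All randomness flows through an explicit seed; equal seeds give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import CensoringError, InvalidArgumentError
from .health import DEFAULT_OMEGA, Lifetable, TTDPrevalence, build_lifetable
from .hexad import Lifeline, Observation

__all__ = [
    "GompertzParams",
    "LogisticTTDParams",
    "gompertz_qx",
    "gompertz_survival",
    "gompertz_lifetable",
    "simulate_lifelines",
    "simulate_panel",
    "censor_at",
    "ttd_prevalence_schedule",
]


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz(-Makeham) hazard mu(x) = a * exp(b x) + makeham.

    ``a`` is the baseline hazard per year at age 0, ``b`` the rate of
    aging (log-hazard slope per year), ``makeham`` an optional
    age-independent background hazard.  Defaults give an adult human
    mortality schedule with modal age at death near 69
    ((1/b) log(b/a) for a = 1e-4, b = 0.1).
    """

    a: float = 1e-4
    b: float = 0.1
    makeham: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.makeham < 0:
            raise InvalidArgumentError(
                f"need a > 0, b > 0, makeham >= 0; got {self}"
            )

    def hazard(self, x):
        return self.a * np.exp(self.b * np.asarray(x, dtype=float)) + self.makeham


@dataclass(frozen=True)
class LogisticTTDParams:
    """Logistic time-to-death prevalence g(t) = g_max / (1 + exp(k (t - t50))).

    ``g_max`` is the asymptotic prevalence approaching death, ``k`` the
    steepness per year, ``t50`` the thanatological age at half-maximum.
    Decreasing in t for k > 0: morbidity concentrates near death.
    """

    g_max: float = 0.6
    k: float = 0.8
    t50: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.g_max <= 1.0:
            raise InvalidArgumentError(f"g_max must be in [0, 1], got {self.g_max}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.g_max / (1.0 + np.exp(self.k * (t - self.t50)))


def gompertz_survival(params: GompertzParams, x) -> np.ndarray:
    """Survivorship S(x) = exp(-(a/b)(e^{bx} - 1) - makeham*x)."""
    x = np.asarray(x, dtype=float)
    return np.exp(
        -(params.a / params.b) * (np.exp(params.b * x) - 1.0) - params.makeham * x
    )


def gompertz_qx(params: GompertzParams, omega: int = DEFAULT_OMEGA) -> np.ndarray:
    """Single-year death probabilities q(x) = 1 - S(x+1)/S(x), x = 0..omega."""
    x = np.arange(omega + 1, dtype=float)
    q = 1.0 - np.exp(
        -(params.a / params.b) * np.exp(params.b * x) * (np.exp(params.b) - 1.0)
        - params.makeham
    )
    q[-1] = 1.0
    return q


def gompertz_lifetable(
    params: GompertzParams, omega: int = DEFAULT_OMEGA, radix: float = 1.0
) -> Lifetable:
    """Lifetable of the Gompertz(-Makeham) schedule closed out at omega."""
    return build_lifetable(qx=gompertz_qx(params, omega), radix=radix, omega=omega)


def _draw_lifespans(n: int, params: GompertzParams, rng: np.random.Generator) -> np.ndarray:
    """Exact inverse-transform lifespans; Makeham as a competing exponential."""
    u = rng.uniform(size=n)
    spans = np.log1p(-(params.b / params.a) * np.log(u)) / params.b
    if params.makeham > 0:
        background = rng.exponential(1.0 / params.makeham, size=n)
        spans = np.minimum(spans, background)
    return spans


def simulate_lifelines(
    n: int,
    cohort_range: tuple[float, float] = (1905.0, 1925.0),
    params: GompertzParams = GompertzParams(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Lifeline]:
    """Draw ``n`` lifelines: uniform birth times, Gompertz lifespans.

    ``cohort_range`` is half-open in decimal years (a width-0 range puts
    every birth at the same instant).  Pass either ``seed`` or an
    existing ``rng``; implicit randomness is refused.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if rng is None:
        if seed is None:
            raise InvalidArgumentError("pass seed= (or rng=); implicit randomness is not allowed")
        rng = np.random.default_rng(seed)
    lo, hi = cohort_range
    if hi < lo:
        raise InvalidArgumentError(f"cohort_range {cohort_range} is reversed")
    births = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
    spans = _draw_lifespans(n, params, rng)
    return [
        Lifeline(id=i, birth=float(b), death=float(b + s))
        for i, (b, s) in enumerate(zip(births, spans))
    ]


def censor_at(lifelines: Sequence[Lifeline], time: float) -> list[Lifeline]:
    """Right-censor a set of lifelines at a follow-up end: deaths after
    ``time`` become unknown (death=None)."""
    return [
        Lifeline(id=l.id, birth=l.birth, death=None)
        if (l.death is None or l.death > time)
        else l
        for l in lifelines
    ]


def simulate_panel(
    lifelines: Sequence[Lifeline],
    wave_interval: float = 2.0,
    obs_window: tuple[float, float] = (1980.0, 2010.0),
    g_params: LogisticTTDParams = LogisticTTDParams(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Observation]:
    """Interview lifelines at regular waves; record a Bernoulli(g(T)) indicator.

    Waves run from the window start in steps of ``wave_interval`` while
    inside the half-open window.  An individual is interviewed at every
    wave with birth <= wave < death; the indicator is 1 with probability
    ``g_params(T)`` where T is the exact time to death at the interview.
    Mortality follow-up is assumed exact, so death times must be known —
    censor *after* generating the panel, not before.
    """
    if wave_interval <= 0:
        raise InvalidArgumentError(f"wave_interval must be positive, got {wave_interval}")
    if rng is None:
        if seed is None:
            raise InvalidArgumentError("pass seed= (or rng=); implicit randomness is not allowed")
        rng = np.random.default_rng(seed)
    censored = [l.id for l in lifelines if l.death is None]
    if censored:
        raise CensoringError(
            f"panel generation needs known death times; censored ids {censored[:5]}..."
        )
    start, end = obs_window
    if end < start:
        raise InvalidArgumentError(f"obs_window {obs_window} is reversed")
    waves = np.arange(start, end, wave_interval)
    births = np.array([l.birth for l in lifelines])
    deaths = np.array([l.death for l in lifelines])
    ids = [l.id for l in lifelines]

    out: list[Observation] = []
    for w in waves:
        alive = np.nonzero((births <= w) & (w < deaths))[0]
        if alive.size == 0:
            continue
        t_left = deaths[alive] - w
        p = g_params(t_left)
        draws = rng.uniform(size=alive.size) < p
        out.extend(
            Observation(id=ids[i], time=float(w), value=float(v))
            for i, v in zip(alive, draws)
        )
    return out


def ttd_prevalence_schedule(
    g_params: LogisticTTDParams, length: int = DEFAULT_OMEGA + 1
) -> TTDPrevalence:
    """The true trajectory sampled at completed thanatological ages.

    Evaluated at mid-interval (t + 1/2), matching the completed-age
    meaning of the discrete schedule.
    """
    t = np.arange(length, dtype=float) + 0.5
    return TTDPrevalence(g_params(t))
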