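"""Binning lifelines and panel observations onto temporal planes.

Double-classified data live on a temporal plane as *cells*: squares when
both axis measures are binned (AP squares of the Lexis diagram, TAL
cells), horizontal parallelograms when the y measure and the derived
measure are binned (e.g. age x birth-cohort), and vertical parallelograms
for the x measure and the derived measure (e.g. period x birth-cohort).
Binning is half-open and floor-based, ``[k*width, (k+1)*width)`` — the
standard completed-years classification; observations exactly at death
fall in the T = 0 row.

:func:`aggregate` turns observations resolved against their lifelines
into a :class:`SurfaceGrid` of per-cell counts and (optionally weighted)
means.  Observations on censored lifelines cannot be placed on
death-anchored planes; they are dropped and counted, never silently lost.
:func:`variation_direction` quantifies whether a surface varies mainly
along rows or columns — e.g. whether prevalence on a TAL surface is a
time-to-death pattern (roughly horizontal contours) rather than an age
pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DomainViolationError,
    InvalidArgumentError,
    MissingMeasureError,
    OutOfRangeError,
    UndefinedStatisticError,
)
from .hexad import DemographicCoordinate, Lifeline, Observation, complete
from .coordinates import PlaneSpec

__all__ = [
    "SurfaceGrid",
    "SHAPE_TAGS",
    "assign_cell",
    "aggregate",
    "cohort_tal_surfaces",
    "variation_direction",
    "VariationShares",
]

SHAPE_TAGS = ("square", "horizontal-parallelogram", "vertical-parallelogram")

#: Measures that must be non-negative wherever they classify a cell.
_NONNEGATIVE = {"A", "T", "L"}


def _classifying_measures(plane: PlaneSpec, shape_tag: str) -> tuple[str, str]:
    """The (first, second) measures that index cells for a shape."""
    if shape_tag == "square":
        return plane.x_measure, plane.y_measure
    if shape_tag == "horizontal-parallelogram":
        return plane.y_measure, plane.derived_measure
    if shape_tag == "vertical-parallelogram":
        return plane.x_measure, plane.derived_measure
    raise InvalidArgumentError(
        f"unknown shape_tag {shape_tag!r}; expected one of {SHAPE_TAGS}"
    )


def assign_cell(
    coord: DemographicCoordinate,
    plane: PlaneSpec,
    width: float = 1.0,
    shape_tag: str = "square",
) -> tuple[int, int]:
    """Cell index (i, j) of a coordinate: i = floor(u/width), j = floor(v/width).

    (u, v) are the two classifying measures of the shape (see
    :data:`SHAPE_TAGS`).  The coordinate is completed first, so any
    derivable measure may be classified.
    """
    if width <= 0:
        raise InvalidArgumentError(f"width must be positive, got {width}")
    coord = complete(coord)
    mu, mv = _classifying_measures(plane, shape_tag)
    out = []
    for m in (mu, mv):
        v = coord.get(m)
        if v is None:
            raise MissingMeasureError(
                f"measure {m} not derivable from {coord!r}"
            )
        if m in _NONNEGATIVE and v < 0:
            raise DomainViolationError(f"{m} = {v:g} is negative")
        out.append(math.floor(v / width))
    return out[0], out[1]


@dataclass
class SurfaceGrid:
    """A binned aggregate over the cells of one temporal plane.

    Cell (i, j) covers ``[i*width, (i+1)*width)`` x ``[j*width, ...)`` in
    the two classifying measures.  ``counts`` holds observation counts,
    ``value_sum``/``weight_sum`` accumulate the (weighted) payload;
    :attr:`values` is the per-cell weighted mean, NaN where empty.
    ``dropped`` counts observations that could not be classified
    (censored lifelines on a death-anchored plane).
    """

    plane: PlaneSpec
    width: float = 1.0
    shape_tag: str = "square"
    i0: int = 0
    j0: int = 0
    counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=np.int64))
    value_sum: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    weight_sum: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    dropped: int = 0

    @property
    def measures(self) -> tuple[str, str]:
        return _classifying_measures(self.plane, self.shape_tag)

    @property
    def values(self) -> np.ndarray:
        """Per-cell weighted mean payload (NaN where no data)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.weight_sum > 0, self.value_sum / self.weight_sum, np.nan)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def cell_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Measure-unit bin edges along the first and second classifier."""
        ni, nj = self.counts.shape
        return (
            (self.i0 + np.arange(ni + 1)) * self.width,
            (self.j0 + np.arange(nj + 1)) * self.width,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of populated cells."""
        mu, mv = self.measures
        ii, jj = np.nonzero(self.counts)
        vals = self.values
        return pd.DataFrame(
            {
                "plane": self.plane.triad,
                "shape": self.shape_tag,
                f"{mu}_bin": (ii + self.i0) * self.width,
                f"{mv}_bin": (jj + self.j0) * self.width,
                "count": self.counts[ii, jj],
                "value": vals[ii, jj],
            }
        )


def _measures_table(
    observations: Sequence[Observation],
    lifelines: Sequence[Lifeline],
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Resolve observations against lifelines; all six measures, vectorized."""
    life = pd.DataFrame(
        {
            "id": [l.id for l in lifelines],
            "C": [l.birth for l in lifelines],
            "D": [np.nan if l.death is None else l.death for l in lifelines],
        }
    )
    if life["id"].duplicated().any():
        dupes = life.loc[life["id"].duplicated(), "id"].tolist()
        raise InvalidArgumentError(f"duplicate lifeline ids: {dupes}")
    obs = pd.DataFrame(
        {
            "id": [o.id for o in observations],
            "P": [o.time for o in observations],
            "value": [np.nan if o.value is None else o.value for o in observations],
            "weight": [o.weight for o in observations],
        }
    )
    df = obs.merge(life, on="id", how="left", validate="many_to_one")
    if df["C"].isna().any():
        orphans = df.loc[df["C"].isna(), "id"].unique().tolist()
        raise InvalidArgumentError(f"observations reference unknown lifelines: {orphans}")
    bad = (df["P"] < df["C"] - eps) | (df["P"] > df["D"] + eps)
    if bad.any():
        raise OutOfRangeError(
            "observation times outside [birth, death] for ids "
            f"{df.loc[bad, 'id'].unique().tolist()}"
        )
    df["A"] = df["P"] - df["C"]
    df["T"] = df["D"] - df["P"]
    df["L"] = df["D"] - df["C"]
    for m in ("A", "T", "L"):
        df[m] = df[m].clip(lower=0.0)  # eps-tolerated boundary noise only
    return df


def aggregate(
    observations: Sequence[Observation],
    lifelines: Sequence[Lifeline],
    plane: PlaneSpec,
    width: float = 1.0,
    statistic: str = "count",
    shape_tag: str = "square",
) -> SurfaceGrid:
    """Bin observations into a :class:`SurfaceGrid` on a temporal plane.

    ``statistic="count"`` needs no payload; ``"mean"`` averages the
    observation values (weighted by observation weights) per cell.
    Observations on censored lifelines are classified when the plane only
    needs birth-anchored measures (A, P, C) and otherwise counted in
    ``grid.dropped``.  An empty input yields an empty grid.
    """
    if width <= 0:
        raise InvalidArgumentError(f"width must be positive, got {width}")
    if statistic not in ("count", "mean"):
        raise InvalidArgumentError(f"statistic must be 'count' or 'mean', got {statistic!r}")
    mu, mv = _classifying_measures(plane, shape_tag)
    grid = SurfaceGrid(plane=plane, width=width, shape_tag=shape_tag)
    if len(observations) == 0:
        return grid

    df = _measures_table(observations, lifelines)
    needs_death = not set((mu, mv)) <= {"A", "P", "C"}
    if needs_death:
        censored = df["D"].isna()
        grid.dropped = int(censored.sum())
        df = df[~censored]
    if statistic == "mean":
        missing = df["value"].isna()
        if missing.any():
            raise InvalidArgumentError(
                f"statistic='mean' requires payload values; {int(missing.sum())} "
                "observation(s) have none"
            )
    if df.empty:
        return grid

    for m in set((mu, mv)) & _NONNEGATIVE:
        if (df[m] < 0).any():
            raise DomainViolationError(f"negative {m} encountered while binning")

    ii = np.floor(df[mu].to_numpy() / width).astype(np.int64)
    jj = np.floor(df[mv].to_numpy() / width).astype(np.int64)
    grid.i0, grid.j0 = int(ii.min()), int(jj.min())
    shape = (int(ii.max()) - grid.i0 + 1, int(jj.max()) - grid.j0 + 1)
    grid.counts = np.zeros(shape, dtype=np.int64)
    grid.value_sum = np.zeros(shape)
    grid.weight_sum = np.zeros(shape)
    np.add.at(grid.counts, (ii - grid.i0, jj - grid.j0), 1)
    if statistic == "mean":
        w = df["weight"].to_numpy(dtype=float)
        np.add.at(grid.value_sum, (ii - grid.i0, jj - grid.j0), w * df["value"].to_numpy())
        np.add.at(grid.weight_sum, (ii - grid.i0, jj - grid.j0), w)
    return grid


def cohort_tal_surfaces(
    observations: Sequence[Observation],
    lifelines: Sequence[Lifeline],
    cohort_width: float = 5.0,
    width: float = 1.0,
    statistic: str = "mean",
    age_range: tuple[float, float] | None = None,
    mapping: str = "cartesian",
) -> list[tuple[str, SurfaceGrid]]:
    """One TAL surface per birth-cohort bin of ``cohort_width`` years.

    Lifelines are partitioned by half-open cohort bins
    ``[k*cohort_width, (k+1)*cohort_width)``; labels read "1905-1909".
    ``age_range`` optionally restricts observations to a chronological age
    window (half-open), e.g. ``(70, 100)``.  Empty cohorts between
    populated ones are returned as empty grids.
    """
    if cohort_width <= 0:
        raise InvalidArgumentError(f"cohort_width must be positive, got {cohort_width}")
    plane = PlaneSpec("TAL", mapping=mapping)
    by_bin: dict[int, list[Lifeline]] = {}
    for life in lifelines:
        by_bin.setdefault(math.floor(life.birth / cohort_width), []).append(life)
    if not by_bin:
        return []
    obs_by_id: dict[object, list[Observation]] = {}
    for o in observations:
        obs_by_id.setdefault(o.id, []).append(o)

    out: list[tuple[str, SurfaceGrid]] = []
    for k in range(min(by_bin), max(by_bin) + 1):
        lo = k * cohort_width
        hi = lo + cohort_width
        label = f"{lo:g}-{hi - 1:g}" if cohort_width > 1 else f"{lo:g}"
        lives = by_bin.get(k, [])
        obs = [o for l in lives for o in obs_by_id.get(l.id, [])]
        if age_range is not None:
            lo_a, hi_a = age_range
            by_id = {l.id: l for l in lives}
            obs = [
                o
                for o in obs
                if lo_a <= o.time - by_id[o.id].birth < hi_a
            ]
        out.append((label, aggregate(obs, lives, plane, width, statistic)))
    return out


@dataclass(frozen=True)
class VariationShares:
    """Count-weighted between-group variance shares of cell means."""

    x_measure: str
    y_measure: str
    share_x: float
    share_y: float

    def share(self, measure: str) -> float:
        if measure == self.x_measure:
            return self.share_x
        if measure == self.y_measure:
            return self.share_y
        raise InvalidArgumentError(
            f"measure {measure!r} does not classify this grid"
        )


def variation_direction(grid: SurfaceGrid) -> VariationShares:
    """How much of a surface's variation runs along each classifying measure.

    For cell means ``m_ij`` with counts ``n_ij``, the total variance is
    the count-weighted variance of the means across cells; the share for
    a measure is the between-group variance of its rows (cells pooled
    over the other measure) divided by that total.  Both shares lie in
    [0, 1]; an exactly flat surface returns 0 for both (0/0 -> 0 by
    convention).  On a TAL surface a share near 1 for T with a small
    share for A is the signature of a time-to-death pattern.
    """
    n = grid.counts.astype(float)
    populated = (n > 0) & (grid.weight_sum > 0)
    if populated.sum() < 2:
        raise UndefinedStatisticError(
            "variation_direction needs at least two populated cells"
        )
    m = np.where(populated, grid.values, 0.0)
    w = np.where(populated, n, 0.0)
    N = w.sum()
    grand = (w * m).sum() / N
    total = (w * (m - grand) ** 2).sum()

    def between(axis: int) -> float:
        wk = w.sum(axis=axis)
        with np.errstate(invalid="ignore", divide="ignore"):
            mk = np.where(wk > 0, (w * m).sum(axis=axis) / np.where(wk > 0, wk, 1.0), 0.0)
        return float((wk * (mk - grand) ** 2).sum())

    if total == 0.0:
        share_i = share_j = 0.0
    else:
        # rows of the first classifier pool over axis 1 and vice versa
        share_i = between(axis=1) / total
        share_j = between(axis=0) / total
    mu, mv = grid.measures
    return VariationShares(x_measure=mu, y_measure=mv, share_x=share_i, share_y=share_j)
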