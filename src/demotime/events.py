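"""Event-duration vector spaces and the graph of time measures.

Any set of ``n >= 2`` dated events (calendar times ``p_1 .. p_n``) implies
``m = n(n-1)/2`` pairwise durations ``d_ij = p_j - p_i``.  Events and
durations together form ``n(n+1)/2`` *time measures*.  The map from events
to durations is linear and is represented here by an integer difference
matrix ``X`` with ``d = X @ p``; ``X`` annihilates constants (row sums are
zero) and has rank ``n - 1``, so there is no linear map back from durations
to events — infinitely many event vectors share one duration vector.

The joint structure is encoded as a *graph of time measures*: ``n + 1``
vertices, with every event edge incident to a single hub vertex and every
duration edge joining two event vertices.  The graph is complete, so each
triangle of mutually connecting edges is a *triad identity* — three
measures any two of which determine the third.  The demographic hexad
(events birth cohort C, period P, death cohort D; durations chronological
age A, lifespan L, thanatological age T) is the ``n = 3`` case, built by
:func:`demographic_graph`.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "EventVector",
    "DurationVector",
    "duration_pairs",
    "difference_matrix",
    "durations",
    "measure_counts",
    "time_graph",
    "demographic_graph",
    "triad_identities",
    "classify_dyads",
    "iso_to_decimal_year",
    "HUB",
]

#: Name of the hub vertex that all event edges share.
HUB = 0


def _check_n(n: int) -> int:
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 2:
        raise InvalidArgumentError(f"need an integer event count n >= 2, got {n!r}")
    return int(n)


def duration_pairs(n: int) -> list[tuple[int, int]]:
    """Ordered (i, j) index pairs, 1-based, grouped by i with j ascending.

    This fixed ordering — (1,2), (1,3), ..., (1,n), (2,3), ..., (n-1,n) —
    is used for every duration vector and for the rows of
    :func:`difference_matrix`.  Any other ordering is an explicit row
    permutation; the duration *set* is unique either way.
    """
    n = _check_n(n)
    return [(i, j) for i in range(1, n) for j in range(i + 1, n + 1)]


def measure_counts(n: int) -> tuple[int, int]:
    """Return ``(m, total)``: duration count n(n-1)/2 and measure count n(n+1)/2."""
    n = _check_n(n)
    m = n * (n - 1) // 2
    return m, n + m


def difference_matrix(n: int) -> np.ndarray:
    """The m x n integer matrix X with ``durations = X @ events``.

    Row k encodes ``d_ij = p_j - p_i`` for the k-th pair of
    :func:`duration_pairs`: one -1 (column i-1), one +1 (column j-1), zeros
    elsewhere.  Integer dtype keeps translation invariance exact.
    """
    n = _check_n(n)
    pairs = duration_pairs(n)
    X = np.zeros((len(pairs), n), dtype=np.int64)
    for row, (i, j) in enumerate(pairs):
        X[row, i - 1] = -1
        X[row, j - 1] = 1
    return X


@dataclass(frozen=True)
class EventVector:
    """``n`` labelled events at real calendar times (decimal years)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(labels) != values.size:
            raise InvalidArgumentError("labels and values must be 1-d and equal length")
        _check_n(values.size)
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError(f"event labels must be unique: {labels}")
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("event times must be finite")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size

    def durations(self) -> "DurationVector":
        return durations(self)


@dataclass(frozen=True)
class DurationVector:
    """``m = n(n-1)/2`` labelled signed durations in pair order."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def m(self) -> int:
        return self.values.size


def durations(p: EventVector | Sequence[float]) -> DurationVector:
    """All pairwise durations of an event vector, in the fixed pair order.

    Durations may be negative: the event order in ``p`` is a labelling
    convention, not a chronology.  Translation invariant — shifting every
    event by the same constant leaves the result unchanged.
    """
    if not isinstance(p, EventVector):
        values = np.asarray(p, dtype=float)
        if values.ndim != 1:
            raise InvalidArgumentError("event vector must be 1-d")
        _check_n(values.size)
        labels = tuple(f"p{i}" for i in range(1, values.size + 1))
        p = EventVector(labels, values)
    X = difference_matrix(p.n)
    pair_labels = tuple(
        f"{p.labels[j - 1]}-{p.labels[i - 1]}" for (i, j) in duration_pairs(p.n)
    )
    return DurationVector(pair_labels, X @ p.values)


# ---------------------------------------------------------------------------
# Graph of time measures


def time_graph(
    labels: Sequence[str], duration_labels: Sequence[str] | None = None
) -> nx.Graph:
    """Build the complete graph of time measures on ``n + 1`` vertices.

    Vertex ``HUB`` (=0) is the hub; event edges run hub -> vertex ``i``
    (1-based, in label order) and carry the event labels; the duration edge
    between vertices ``i`` and ``j`` carries ``duration_labels`` in pair
    order, defaulting to ``"(i,j)"``.  Every edge stores its measure name
    in the ``"measure"`` attribute.
    """
    labels = tuple(labels)
    n = _check_n(len(labels))
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError(f"event labels must be unique: {labels}")
    pairs = duration_pairs(n)
    if duration_labels is None:
        duration_labels = tuple(f"({i},{j})" for i, j in pairs)
    duration_labels = tuple(duration_labels)
    if len(duration_labels) != len(pairs):
        raise InvalidArgumentError(
            f"expected {len(pairs)} duration labels, got {len(duration_labels)}"
        )
    all_labels = labels + duration_labels
    if len(set(all_labels)) != len(all_labels):
        raise InvalidArgumentError(f"measure labels must be unique: {all_labels}")

    g = nx.Graph(n_events=n)
    g.add_nodes_from(range(n + 1))
    for i, lab in enumerate(labels, start=1):
        g.add_edge(HUB, i, measure=lab, kind="event")
    for (i, j), lab in zip(pairs, duration_labels):
        g.add_edge(i, j, measure=lab, kind="duration")
    return g


def demographic_graph() -> nx.Graph:
    """The hexad graph: events (C, P, D) with durations (A, L, T).

    With events ordered (C, P, D), the pair order (1,2), (1,3), (2,3)
    makes the durations P-C = A (chronological age), D-C = L (lifespan)
    and D-P = T (thanatological age).
    """
    return time_graph(("C", "P", "D"), ("A", "L", "T"))


def triad_identities(graph: nx.Graph) -> list[frozenset[str]]:
    """All triad identities of a time-measure graph.

    Each triangle of mutually connecting edges is one triad identity; the
    graph is complete, so there are C(n+1, 3) of them.  Returned as
    frozensets of the three measure labels, in vertex-triple order.
    """
    out = []
    for u, v, w in itertools.combinations(sorted(graph.nodes), 3):
        if graph.has_edge(u, v) and graph.has_edge(u, w) and graph.has_edge(v, w):
            out.append(
                frozenset(
                    (
                        graph.edges[u, v]["measure"],
                        graph.edges[u, w]["measure"],
                        graph.edges[v, w]["measure"],
                    )
                )
            )
    return out


def classify_dyads(graph: nx.Graph) -> dict[frozenset[str], str | None]:
    """Map every unordered measure pair to its derived measure, or None.

    Two measures are an *informative dyad* when their edges share a
    triangle; the third edge of that triangle is the derived measure.
    Edges with no common vertex share no triangle and the dyad is
    uninformative (for the hexad: LP, CT and AD).
    """
    by_label: dict[str, tuple[int, int]] = {}
    for u, v, data in graph.edges(data=True):
        by_label[data["measure"]] = (u, v)
    out: dict[frozenset[str], str | None] = {}
    for lab1, lab2 in itertools.combinations(sorted(by_label), 2):
        e1, e2 = by_label[lab1], by_label[lab2]
        shared = set(e1) & set(e2)
        if len(shared) == 1:
            a = (set(e1) - shared).pop()
            b = (set(e2) - shared).pop()
            out[frozenset((lab1, lab2))] = graph.edges[a, b]["measure"]
        else:
            out[frozenset((lab1, lab2))] = None
    return out


def dyad_derived(graph: nx.Graph, measure1: str, measure2: str) -> str | None:
    """Derived measure of one dyad (None when uninformative)."""
    table = classify_dyads(graph)
    key = frozenset((measure1, measure2))
    if key not in table:
        known = sorted({m for pair in table for m in pair})
        raise InvalidArgumentError(
            f"unknown measure pair ({measure1}, {measure2}); measures are {known}"
        )
    return table[key]


def iso_to_decimal_year(date: str | _dt.date) -> float:
    """Convert an ISO date to a decimal year on a 365.25-day year.

    The value is ``year + (days since 1 January) / 365.25``; sub-day
    precision is not represented.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    day_of_year = (date - _dt.date(date.year, 1, 1)).days
    return date.year + day_of_year / 365.25
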