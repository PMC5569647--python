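"""Temporal planes and the 3-D tetrahedral embedding of the hexad.

Each triad identity extends to a *temporal plane*, an (x, y) mapping of
two of its measures with the third appearing as a family of diagonals.
Two mappings are supported:

* **cartesian** — each measure maps directly to its axis with a unity
  aspect ratio.  A unit step of the derived measure then runs along a 45
  degree diagonal of length sqrt(2): the familiar stretching of cohort
  lines on the Lexis diagram.
* **isotropic** — the x measure maps along (1, 0) and the y measure
  along (1/2, sqrt(3)/2), i.e. the axes meet at 60 degrees.  Unit steps
  of all three triad measures then have equal spatial length 1, as in
  ternary/barycentric coordinates.

The full hexad embeds in 3-D by the isotropic extension: positions are
``P*e_P + A*e_A + T*e_T`` with the three basis vectors pairwise at 60
degrees.  The six vectors {e_P, e_A, e_T, e_A - e_P, e_T - e_P,
e_T - e_A} are the edge directions of a regular tetrahedron, one per
measure (C: e_A - e_P, D: e_T - e_P, L: e_T - e_A), so a unit step of
*any* measure has spatial length 1.  Each tetrahedron face carries one
triad identity, and the coordinate cross-sections parallel to a face
are exact isometric copies of that triad's 2-D isotropic plane: fixed T
gives APC planes (T = 0 is the base), fixed A gives TPD planes, and
fixed P gives the synthetic (period cross-section) TAL triangles; the
outer face is spanned by the C and D edge directions of the LCD
identity.  The origin, handedness and the choice of e_P along x are
conventions of this package; any rotation is equally isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import (
    CensoringError,
    InvalidArgumentError,
    MissingMeasureError,
)
from .hexad import DemographicCoordinate, Lifeline, complete, measures_at

__all__ = [
    "TRIADS",
    "DEFAULT_ORIENTATION",
    "PlaneSpec",
    "project_plane",
    "unit_step_images",
    "derived_measure_stretch",
    "BASIS_3D",
    "MEASURE_GENERATORS_3D",
    "embed3d",
    "invert_embed3d",
    "lifeline_path",
]

#: The four triad identities and their member measures.
TRIADS: dict[str, frozenset[str]] = {
    "APC": frozenset("APC"),
    "TPD": frozenset("TPD"),
    "TAL": frozenset("TAL"),
    "LCD": frozenset("LCD"),
}

#: Default (x, y) orientation of each plane, matching common usage:
#: the Lexis diagram puts period on x and age on y, etc.
DEFAULT_ORIENTATION: dict[str, tuple[str, str]] = {
    "APC": ("P", "A"),
    "TPD": ("P", "T"),
    "TAL": ("A", "T"),
    "LCD": ("C", "L"),
}

_SQRT3 = np.sqrt(3.0)

#: Isotropic in-plane images of a unit step along x and along y.
_ISO_X = np.array([1.0, 0.0])
_ISO_Y = np.array([0.5, _SQRT3 / 2.0])


@dataclass(frozen=True)
class PlaneSpec:
    """A temporal plane: triad, axis assignment and mapping.

    ``x_measure``/``y_measure`` default to the conventional orientation
    (AP(C), TP(D), TA(L), LC(D)); pass them explicitly for rotations such
    as AC(P) or CP(A).
    """

    triad: str
    x_measure: str | None = None
    y_measure: str | None = None
    mapping: str = "cartesian"

    def __post_init__(self):
        triad = self.triad.upper()
        if triad not in TRIADS:
            raise InvalidArgumentError(
                f"unknown triad {self.triad!r}; expected one of {sorted(TRIADS)}"
            )
        object.__setattr__(self, "triad", triad)
        x, y = DEFAULT_ORIENTATION[triad]
        if self.x_measure is not None:
            x = self.x_measure.upper()
        if self.y_measure is not None:
            y = self.y_measure.upper()
        members = TRIADS[triad]
        if x not in members or y not in members:
            raise InvalidArgumentError(
                f"axes ({x}, {y}) must belong to triad {triad}"
            )
        if x == y:
            raise InvalidArgumentError("x and y must be different measures")
        object.__setattr__(self, "x_measure", x)
        object.__setattr__(self, "y_measure", y)
        if self.mapping not in ("cartesian", "isotropic"):
            raise InvalidArgumentError(
                f"mapping must be 'cartesian' or 'isotropic', got {self.mapping!r}"
            )

    @property
    def derived_measure(self) -> str:
        """The triad member not assigned to an axis."""
        (rest,) = TRIADS[self.triad] - {self.x_measure, self.y_measure}
        return rest


def _axis_images(spec: PlaneSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.mapping == "cartesian":
        return np.array([1.0, 0.0]), np.array([0.0, 1.0])
    return _ISO_X.copy(), _ISO_Y.copy()


def unit_step_images(spec: PlaneSpec) -> dict[str, np.ndarray]:
    """Spatial images of a unit step of each triad measure on the plane.

    The derived measure's direction is the difference ``u_y - u_x`` of the
    axis images — the third edge of the coordinate triangle.  Its sign is
    a convention; only its direction and length matter.
    """
    ux, uy = _axis_images(spec)
    return {
        spec.x_measure: ux,
        spec.y_measure: uy,
        spec.derived_measure: uy - ux,
    }


def derived_measure_stretch(spec: PlaneSpec) -> float:
    """Spatial length of one unit of the derived (diagonal) measure.

    sqrt(2) under the cartesian mapping — the classic stretching of the
    cohort diagonal on the Lexis diagram — and exactly 1 under the
    isotropic mapping.
    """
    steps = unit_step_images(spec)
    return float(np.linalg.norm(steps[spec.derived_measure]))


def project_plane(coord: DemographicCoordinate, spec: PlaneSpec) -> np.ndarray:
    """Project a coordinate onto a temporal plane; returns (x, y).

    Cartesian mapping returns the two measure values directly; isotropic
    mapping places them along axes at 60 degrees.  Both axis measures must
    be present — run :func:`demotime.hexad.complete` first if needed.
    """
    xv = coord.get(spec.x_measure)
    yv = coord.get(spec.y_measure)
    if xv is None or yv is None:
        missing = [m for m, v in ((spec.x_measure, xv), (spec.y_measure, yv)) if v is None]
        raise MissingMeasureError(
            f"measure(s) {missing} absent from {coord!r}; complete() the coordinate first"
        )
    ux, uy = _axis_images(spec)
    return xv * ux + yv * uy


# ---------------------------------------------------------------------------
# 3-D embedding

#: Unit basis vectors at mutual 60 degrees: columns are e_P, e_A, e_T.
E_P = np.array([1.0, 0.0, 0.0])
E_A = np.array([0.5, _SQRT3 / 2.0, 0.0])
E_T = np.array([0.5, _SQRT3 / 6.0, np.sqrt(6.0) / 3.0])
BASIS_3D = np.column_stack([E_P, E_A, E_T])

#: Tetrahedron edge direction associated with each of the six measures.
MEASURE_GENERATORS_3D: dict[str, np.ndarray] = {
    "P": E_P,
    "A": E_A,
    "T": E_T,
    "C": E_A - E_P,
    "D": E_T - E_P,
    "L": E_T - E_A,
}

#: Faces of the embedding tetrahedron (vertex fan {0, e_P, e_A, e_T}),
#: one per triad: the face spanned by two hub edges carries their triad.
TETRAHEDRON_FACES: dict[str, tuple[str, ...]] = {
    "APC": ("origin", "e_P", "e_A"),
    "TPD": ("origin", "e_P", "e_T"),
    "TAL": ("origin", "e_A", "e_T"),
    "LCD": ("e_P", "e_A", "e_T"),
}


def embed3d(coord: DemographicCoordinate) -> np.ndarray:
    """Isotropic 3-D position ``P*e_P + A*e_A + T*e_T`` of a coordinate.

    Requires a complete coordinate (all six measures present or
    derivable); raises :class:`MissingMeasureError` otherwise.
    """
    coord = complete(coord)
    if not coord.is_complete():
        missing = sorted(set("APCTDL") - coord.present())
        raise MissingMeasureError(
            f"coordinate is not fully determined; missing {missing}"
        )
    pat = np.array([coord.P, coord.A, coord.T])
    return BASIS_3D @ pat


def invert_embed3d(point: Iterable[float]) -> DemographicCoordinate:
    """Recover the full coordinate from a 3-D embedded position."""
    point = np.asarray(list(point), dtype=float)
    if point.shape != (3,):
        raise InvalidArgumentError("expected a 3-vector")
    P, A, T = np.linalg.solve(BASIS_3D, point)
    return complete(DemographicCoordinate(P=float(P), A=float(A), T=float(T)))


# ---------------------------------------------------------------------------
# Lifeline paths


def lifeline_path(
    lifeline: Lifeline,
    spec: PlaneSpec | str,
    step: float = 1.0,
    until: float | None = None,
) -> np.ndarray:
    """Sample a lifeline's trajectory on a plane (or in 3-D) at ``step`` years.

    Returns an array of points, one row per sampled observation time from
    birth to death inclusive.  On the APC plane the path ascends along the
    birth-cohort diagonal (censored lifelines allowed, ended at ``until``);
    on TPD it descends to T = 0; on TAL it descends the constant-L
    diagonal; on LCD the whole life is a single point.  Pass ``spec="3d"``
    for the tetrahedral embedding, where a lifeline is a straight segment.
    Death-anchored targets require an uncensored lifeline.
    """
    if step <= 0:
        raise InvalidArgumentError(f"step must be positive, got {step}")
    want_3d = isinstance(spec, str)
    if want_3d and spec.lower() != "3d":
        raise InvalidArgumentError(f"unknown target {spec!r}; use a PlaneSpec or '3d'")

    death_anchored = want_3d or spec.triad != "APC"
    if lifeline.censored and death_anchored:
        raise CensoringError(
            f"lifeline {lifeline.id!r} is censored; its position on a "
            "death-anchored target is unknown"
        )

    if not want_3d and spec.triad == "LCD":
        coord = measures_at(lifeline, lifeline.death)
        return project_plane(coord, spec)[np.newaxis, :]

    end = lifeline.death if lifeline.death is not None else until
    if end is None:
        raise InvalidArgumentError(
            "censored lifeline on APC needs an explicit 'until' time"
        )
    times = np.arange(lifeline.birth, end, step)
    if times.size == 0 or times[-1] < end:
        times = np.append(times, end)

    points = []
    for t in times:
        coord = measures_at(lifeline, float(t))
        points.append(embed3d(coord) if want_3d else project_plane(coord, spec))
    return np.asarray(points)
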