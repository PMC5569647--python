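"""Quick-look plots: lifeline diagrams and surface heatmaps.

Presentation helpers only — colors, contour breaks and layout carry no
semantics and are not covered by the test suite.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .coordinates import PlaneSpec, lifeline_path
from .hexad import Lifeline
from .surfaces import SurfaceGrid

__all__ = ["plot_lifelines", "plot_surface"]


def plot_lifelines(
    lifelines: Sequence[Lifeline],
    spec: PlaneSpec,
    ax=None,
    until: float | None = None,
):
    """Draw lifelines on a temporal plane: birth as a filled circle,
    death as a crossed circle, the LCD plane as points."""
    if ax is None:
        _, ax = plt.subplots()
    for life in lifelines:
        pts = np.atleast_2d(lifeline_path(life, spec, until=until))
        ax.plot(pts[:, 0], pts[:, 1], color="black", lw=1)
        ax.plot(pts[0, 0], pts[0, 1], "o", color="black", ms=4)
        if not life.censored:
            ax.plot(pts[-1, 0], pts[-1, 1], "o", mfc="white", mec="black", ms=5)
            ax.plot(pts[-1, 0], pts[-1, 1], "x", color="black", ms=5)
    ax.set_xlabel(spec.x_measure)
    ax.set_ylabel(spec.y_measure)
    ax.set_title(f"{spec.triad} plane ({spec.mapping})")
    return ax


def plot_surface(
    grid: SurfaceGrid,
    ax=None,
    breaks: Sequence[float] = (0.1, 0.2, 0.3, 0.4),
    cmap: str = "RdPu",
    vmin: float = 0.0,
    vmax: float | None = None,
):
    """Heatmap of per-cell means with contour lines at ``breaks``."""
    if ax is None:
        _, ax = plt.subplots()
    xe, ye = grid.cell_edges()
    vals = grid.values
    mesh = ax.pcolormesh(xe, ye, vals.T, cmap=cmap, vmin=vmin, vmax=vmax)
    if np.isfinite(vals).sum() > 3:
        xc = 0.5 * (xe[:-1] + xe[1:])
        yc = 0.5 * (ye[:-1] + ye[1:])
        with np.errstate(invalid="ignore"):
            ax.contour(xc, yc, vals.T, levels=sorted(breaks), colors="black", linewidths=0.6)
    plt.colorbar(mesh, ax=ax, label="value")
    mu, mv = grid.measures
    ax.set_xlabel(mu)
    ax.set_ylabel(mv)
    return ax
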