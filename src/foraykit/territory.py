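"""Territory delineation: 95% MCP of intra-territorial fixes and the river
bank-length size measure.

Territory size is expressed as river bank length (km): the span of
centerline chainage covered by the MCP-retained fixes.  Bank length, not
hull area, is the ecologically meaningful size for a strictly riparian
central-place forager whose range hugs the shoreline of a meandering
river — an area measure would count unused land inside meander loops.

Foray fixes must not enter the MCP (they would grossly inflate it), yet
forays are defined relative to the territory border: the circularity is
resolved by fixed-point iteration (delineate -> classify -> relabel until
labels stabilise).  When field-confirmed territory polygons are already
present in the landscape they are used directly and the iteration is
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon

from .forays import DEFAULT_BUFFER_M, classify_fixes
from .geometry import mcp_retained_indices, convex_hull
from .io import Landscape

__all__ = ["Territory", "delineate", "refine_with_forays", "home_territory_id"]

DEFAULT_MCP_FRACTION = 0.95


@dataclass
class Territory:
    """A family territory: polygon plus bank-length size."""

    territory_id: str
    polygon: Polygon
    bank_length_km: float
    owner_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("territory polygon invalid or degenerate")


def bank_length_km(points_xy, centerline: LineString) -> float:
    """Chainage span (km) of a set of fixes projected onto the centerline.
    Invariant to reversing the centerline's vertex order."""
    pts = shapely.points(np.asarray(points_xy, dtype=float))
    chain = shapely.line_locate_point(centerline, pts)
    return float(chain.max() - chain.min()) / 1000.0


def delineate(
    fixes: pd.DataFrame,
    centerline: LineString,
    fraction: float = DEFAULT_MCP_FRACTION,
    territory_id: str = "focal",
    owner_ids: list[str] | None = None,
) -> Territory:
    """MCP territory from (non-foray) fixes.

    The polygon is the ``fraction`` MCP of fix locations; bank length is
    the chainage span of the MCP-retained fixes along the centerline.
    """
    if "movement_type" in fixes.columns:
        fixes = fixes[fixes["movement_type"] != "foray"]
    xy = fixes[["x", "y"]].values
    idx = mcp_retained_indices(xy, fraction)
    poly = convex_hull(xy[idx])
    return Territory(
        territory_id=territory_id,
        polygon=poly,
        bank_length_km=bank_length_km(xy[idx], centerline),
        owner_ids=owner_ids or [],
    )


def home_territory_id(fixes: pd.DataFrame, landscape: Landscape) -> str | None:
    """The landscape territory containing the most fixes (the individual's
    home), or None if no territory contains any fix."""
    pts = shapely.points(fixes["x"].values, fixes["y"].values)
    best, best_n = None, 0
    for tid in sorted(landscape.territories):
        n = int(shapely.covers(landscape.territories[tid], pts).sum())
        if n > best_n:
            best, best_n = tid, n
    return best


def refine_with_forays(
    fixes: pd.DataFrame,
    landscape: Landscape,
    focal_id: str,
    home_tid: str | None = None,
    fraction: float = DEFAULT_MCP_FRACTION,
    buffer_m: float = DEFAULT_BUFFER_M,
    max_iter: int = 10,
) -> tuple[Territory, pd.DataFrame, int, bool]:
    """Jointly delineate a territory and label forays by fixed-point
    iteration.

    Starting from all-intra labels: (1) delineate the MCP from the current
    intra fixes, (2) classify every fix against that polygon and the
    neighbour territories, (3) relabel; stop when the labels no longer
    change, or after ``max_iter`` passes (non-convergence returns the last
    iterate with ``converged=False``).

    Returns ``(territory, labelled fixes, n_iterations, converged)``.
    """
    fixes = fixes.copy().reset_index(drop=True)
    if home_tid is None:
        home_tid = home_territory_id(fixes, landscape)
    neighbors = landscape.neighbor_territories(home_tid)
    labels = np.full(len(fixes), "intra", dtype=object)
    territory = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        intra = fixes[labels == "intra"]
        territory = delineate(
            intra.drop(columns="movement_type", errors="ignore"),
            landscape.centerline,
            fraction,
            territory_id=home_tid or focal_id,
            owner_ids=[focal_id],
        )
        new_labels = classify_fixes(fixes, territory.polygon, neighbors, buffer_m)
        if (new_labels == labels).all():
            converged = True
            break
        labels = new_labels
    fixes["movement_type"] = labels
    return territory, fixes, n_iter, converged
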