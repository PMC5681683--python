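"""Movement metrics contrasting forays with intra-territorial movement:
land/water assignment, hourly travel speed, distance from the shore.

Travel speed follows the telemetry convention of straight-line distance
between consecutive fixes per hour.  Intra-territorial speed can be
restricted to consecutive water-water fix pairs (the conservative
convention: the animals travel faster in water, and spend more time in
water on forays, so mixing media would exaggerate the contrast); foray
speed always uses all fixes because forays yield too few positions to
split by medium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "DEFAULT_MAX_GAP_MIN",
    "SpeedRecord",
    "classify_medium",
    "travel_speed",
    "distance_from_shore",
    "proportion_in_water",
]

DEFAULT_MAX_GAP_MIN = 20.0


@dataclass
class SpeedRecord:
    """Travel speed over one clock hour for one individual/movement type."""

    individual_id: str
    hour_start: pd.Timestamp
    speed_m_per_hr: float
    movement_type: str
    media_used: str  # "water_only" | "all"
    n_pairs: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["hour_start"] = self.hour_start.isoformat()
        return d


def classify_medium(fixes: pd.DataFrame, water: Polygon) -> np.ndarray:
    """Label each fix ``"water"`` or ``"land"``; points on the shoreline
    count as water."""
    pts = shapely.points(fixes["x"].values, fixes["y"].values)
    return np.where(shapely.covers(water, pts), "water", "land")


def _pairs(fixes: pd.DataFrame, max_gap_min: float, water_only: bool):
    """(t_start, minutes, metres) for each usable consecutive fix pair."""
    ts = fixes["timestamp"].to_numpy()
    xy = fixes[["x", "y"]].values
    medium = fixes["medium"].to_numpy() if "medium" in fixes.columns else None
    out = []
    for i in range(len(fixes) - 1):
        gap = (ts[i + 1] - ts[i]) / np.timedelta64(60, "s")
        if gap <= 0 or gap > max_gap_min:
            continue
        if water_only and (medium is None or medium[i] != "water" or medium[i + 1] != "water"):
            continue
        dist = float(np.hypot(*(xy[i + 1] - xy[i])))
        out.append((pd.Timestamp(ts[i]), float(gap), dist))
    return out


def travel_speed(
    fixes: pd.DataFrame,
    movement_type: str,
    media_used: str = "all",
    max_gap_min: float = DEFAULT_MAX_GAP_MIN,
    method: str = "hourly",
) -> list[SpeedRecord]:
    """Travel speeds for one individual's fixes of one movement type.

    ``method="hourly"`` (default) sums step distances of consecutive fix
    pairs starting within each clock hour (pairs separated by more than
    ``max_gap_min`` — dropped fixes — are excluded) and rescales by the
    covered minutes to m/hr.  ``method="per_step"`` instead emits one
    instantaneous record (distance / gap) per pair.

    ``media_used="water_only"`` keeps only consecutive water-water pairs and
    is intended for intra-territorial movement.
    """
    if media_used not in ("all", "water_only"):
        raise ValueError("media_used must be 'all' or 'water_only'")
    if media_used == "water_only" and movement_type == "foray":
        raise ValueError("water_only speed applies to intra-territorial movement")
    sub = fixes[fixes["movement_type"] == movement_type]
    if sub.empty:
        return []
    iid = str(sub["individual_id"].iloc[0])
    pairs = _pairs(sub, max_gap_min, media_used == "water_only")
    records: list[SpeedRecord] = []
    if method == "per_step":
        for t0, gap, dist in pairs:
            records.append(
                SpeedRecord(iid, t0, dist * 60.0 / gap, movement_type, media_used, 1)
            )
        return records
    if method != "hourly":
        raise ValueError("method must be 'hourly' or 'per_step'")
    by_hour: dict[pd.Timestamp, list] = {}
    for t0, gap, dist in pairs:
        by_hour.setdefault(t0.floor("h"), []).append((gap, dist))
    for hour in sorted(by_hour):
        entries = by_hour[hour]
        if len(entries) < 1:
            continue
        minutes = sum(g for g, _ in entries)
        metres = sum(d for _, d in entries)
        # an hour needs >=2 fixes, i.e. >=1 usable pair, to yield a speed
        records.append(
            SpeedRecord(
                iid, hour, metres * 60.0 / minutes, movement_type, media_used,
                len(entries),
            )
        )
    return records


def distance_from_shore(fixes: pd.DataFrame, water: Polygon) -> np.ndarray:
    """Perpendicular distance (m) from each land fix to the shoreline.

    Precondition: every fix is land-labelled (a water fix is an error)."""
    if "medium" in fixes.columns and (fixes["medium"] == "water").any():
        raise ValueError("distance_from_shore applies to land fixes only")
    pts = shapely.points(fixes["x"].values, fixes["y"].values)
    return shapely.distance(water.boundary, pts)


def proportion_in_water(fixes: pd.DataFrame) -> float:
    """Share of fixes labelled water (order-invariant)."""
    if len(fixes) == 0:
        raise ValueError("proportion_in_water undefined for empty input")
    return float((fixes["medium"] == "water").mean())
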