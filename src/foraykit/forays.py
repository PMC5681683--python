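"""Rule-based extra-territorial foray detection and per-foray metrics.

A fix is part of a foray when all three of the classic criteria hold: it
lies outside the focal individual's territory polygon, more than a buffer
(default 100 m, absorbing territory overlap and GPS error) from that
polygon's border, and inside some other family group's territory.  A fix
outside the home range but within the buffer, or in no known territory, is
still intra-territorial.

Maximal runs of consecutive foray fixes form one foray; because no fixes
are scheduled during the daytime (07:00-19:00), a foray whose animal lays
up outside its territory over the day continues seamlessly into the next
night and is flagged ``spans_multiple_nights``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .geometry import distance_to_boundary
from .io import ACTIVITY_END, ACTIVITY_START, Deployment, Landscape, night_of

__all__ = [
    "DEFAULT_BUFFER_M",
    "DEFAULT_INTERVAL_MIN",
    "ForaySegment",
    "IndividualSummary",
    "classify_fixes",
    "segment",
    "active_minutes",
    "foray_duration",
    "foray_distance",
    "count_intruded",
    "build_segments",
    "summarize_individual",
    "segments_to_frame",
]

DEFAULT_BUFFER_M = 100.0
DEFAULT_INTERVAL_MIN = 15.0
#: Scheduled active minutes per night (19:00-07:00).
NIGHT_MINUTES = 12 * 60


@dataclass
class ForaySegment:
    """One extra-territorial excursion (a maximal run of foray fixes)."""

    individual_id: str
    fixes: pd.DataFrame
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    duration_min: float
    active_duration_min: float
    distance_m: float
    territories_intruded: frozenset[str]
    spans_multiple_nights: bool
    foray_index: int = 0

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def to_dict(self) -> dict:
        return {
            "individual_id": self.individual_id,
            "foray_index": self.foray_index,
            "t_start": self.t_start.isoformat(),
            "t_end": self.t_end.isoformat(),
            "n_fixes": self.n_fixes,
            "duration_min": self.duration_min,
            "active_duration_min": self.active_duration_min,
            "distance_m": self.distance_m,
            "n_territories": len(self.territories_intruded),
            "territories_intruded": sorted(self.territories_intruded),
            "spans_multiple_nights": self.spans_multiple_nights,
        }


@dataclass
class IndividualSummary:
    """Per-deployment foray statistics plus model covariates."""

    individual_id: str
    status: str
    age: float
    season: str
    territory_size_km: float
    n_fixes: int
    tracking_nights: int
    n_forays: int
    forays_per_week: float
    pct_active_time_on_forays: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# classification


def classify_fixes(
    fixes: pd.DataFrame,
    focal: Polygon,
    neighbors: dict[str, Polygon],
    buffer_m: float = DEFAULT_BUFFER_M,
) -> np.ndarray:
    """Label each fix ``"intra"`` or ``"foray"``.

    foray  <=>  outside ``focal``  AND  >`buffer_m` from its border  AND
    inside at least one neighbour territory.  Boundary points count as
    inside; the buffer comparison is strict (exactly 100 m out is intra).
    """
    pts = shapely.points(fixes["x"].values, fixes["y"].values)
    inside_focal = shapely.covers(focal, pts)
    dist_border = shapely.distance(shapely.get_exterior_ring(focal), pts)
    in_neighbor = np.zeros(len(fixes), dtype=bool)
    for poly in neighbors.values():
        in_neighbor |= shapely.covers(poly, pts)
    is_foray = (~inside_focal) & (dist_border > buffer_m) & in_neighbor
    return np.where(is_foray, "foray", "intra")


# ---------------------------------------------------------------------------
# segmentation and per-foray metrics


def segment(fixes: pd.DataFrame, interval_min: float = DEFAULT_INTERVAL_MIN) -> list[ForaySegment]:
    """Cut one individual's labelled, time-sorted fixes into forays.

    A foray is a maximal run of consecutive foray-labelled fixes with no
    intervening intra fix.  Since the GPS sleeps 07:00-19:00, a run ending
    at the last fix of one night and resuming at the first fix of the next
    merges into a single multi-night segment whose duration includes the
    (unobserved) daytime.  Metrics needing geometry (distance, intrusions)
    are filled by :func:`build_segments`.
    """
    labels = fixes["movement_type"].values
    segments: list[ForaySegment] = []
    run_start = None
    idx = fixes.index.to_numpy()
    for i in range(len(fixes) + 1):
        on_foray = i < len(fixes) and labels[i] == "foray"
        if on_foray and run_start is None:
            run_start = i
        elif not on_foray and run_start is not None:
            rows = fixes.loc[idx[run_start:i]]
            t0 = rows["timestamp"].iloc[0]
            t1 = rows["timestamp"].iloc[-1]
            dur, active = foray_duration_times(t0, t1, interval_min)
            segments.append(
                ForaySegment(
                    individual_id=str(rows["individual_id"].iloc[0]),
                    fixes=rows,
                    t_start=t0,
                    t_end=t1,
                    duration_min=dur,
                    active_duration_min=active,
                    distance_m=float("nan"),
                    territories_intruded=frozenset(),
                    spans_multiple_nights=night_of(t0) != night_of(t1),
                    foray_index=len(segments) + 1,
                )
            )
            run_start = None
    return segments


def active_minutes(t0, t1) -> float:
    """Minutes of [t0, t1] that fall inside activity windows (19:00-07:00),
    i.e. elapsed time minus any daytime (07:00-19:00) portions."""
    t0, t1 = pd.Timestamp(t0), pd.Timestamp(t1)
    if t1 < t0:
        raise ValueError("t1 before t0")
    total = (t1 - t0).total_seconds() / 60.0
    day = t0.normalize()
    while day <= t1.normalize():
        day_start = day + timedelta(hours=ACTIVITY_END.hour)
        day_end = day + timedelta(hours=ACTIVITY_START.hour)
        lo = max(t0, day_start)
        hi = min(t1, day_end)
        if hi > lo:
            total -= (hi - lo).total_seconds() / 60.0
        day += timedelta(days=1)
    return total


def foray_duration_times(t0, t1, interval_min: float = DEFAULT_INTERVAL_MIN) -> tuple[float, float]:
    """(full elapsed, active-time-only) duration in minutes.

    Both are floored at one sampling interval so a single-fix foray counts
    15 min (0.25 hr); a multi-night foray's full duration includes the
    daytime gap while the active duration does not.
    """
    elapsed = (pd.Timestamp(t1) - pd.Timestamp(t0)).total_seconds() / 60.0
    active = active_minutes(t0, t1)
    return max(elapsed, interval_min), max(active, interval_min)


def foray_duration(seg: ForaySegment, interval_min: float = DEFAULT_INTERVAL_MIN) -> float:
    """Full elapsed duration (min) of a segment; see
    :func:`foray_duration_times` for the active-only variant."""
    return foray_duration_times(seg.t_start, seg.t_end, interval_min)[0]


def foray_distance(seg_or_fixes, focal: Polygon) -> float:
    """Path length of a foray (m): straight-line distances between
    consecutive foray fixes, plus the distance from the territory border to
    the first and to the last fix."""
    fixes = seg_or_fixes.fixes if isinstance(seg_or_fixes, ForaySegment) else seg_or_fixes
    xy = fixes[["x", "y"]].values
    steps = float(np.hypot(*(np.diff(xy, axis=0).T)).sum()) if len(xy) > 1 else 0.0
    d_first = distance_to_boundary(xy[0], focal)
    d_last = distance_to_boundary(xy[-1], focal)
    return steps + d_first + d_last


def count_intruded(seg_or_fixes, landscape: Landscape, focal_id: str | None) -> frozenset[str]:
    """Identifiers of the non-focal territories containing >=1 foray fix."""
    fixes = seg_or_fixes.fixes if isinstance(seg_or_fixes, ForaySegment) else seg_or_fixes
    pts = shapely.points(fixes["x"].values, fixes["y"].values)
    hit = set()
    for tid, poly in landscape.neighbor_territories(focal_id).items():
        if shapely.covers(poly, pts).any():
            hit.add(tid)
    return frozenset(hit)


def build_segments(
    fixes: pd.DataFrame,
    focal_polygon: Polygon,
    landscape: Landscape,
    focal_territory_id: str | None,
    interval_min: float = DEFAULT_INTERVAL_MIN,
) -> list[ForaySegment]:
    """Segment one individual's labelled fixes and fill in every per-foray
    metric (distance, intruded territory set)."""
    segs = segment(fixes, interval_min)
    for s in segs:
        s.distance_m = foray_distance(s, focal_polygon)
        s.territories_intruded = count_intruded(s, landscape, focal_territory_id)
    return segs


def summarize_individual(
    deployment: Deployment,
    segments: list[ForaySegment],
    fixes: pd.DataFrame,
    territory_size_km: float,
    interval_min: float = DEFAULT_INTERVAL_MIN,
    coverage: str = "scheduled",
) -> IndividualSummary:
    """Collapse a deployment to the covariate row used by the count models.

    ``forays_per_week`` divides the foray count by tracking nights / 7;
    ``pct_active_time_on_forays`` is the active-time foray minutes over the
    total active tracking time — scheduled coverage assumes the full 720
    min per tracked night, ``"realized"`` uses the retained fix count times
    the sampling interval.
    """
    if coverage not in ("scheduled", "realized"):
        raise ValueError("coverage must be 'scheduled' or 'realized'")
    nights = {night_of(t) for t in fixes["timestamp"]}
    n_nights = len(nights)
    n_forays = len(segments)
    per_week = n_forays / (n_nights / 7.0) if n_nights else 0.0
    if coverage == "scheduled":
        total_active = n_nights * NIGHT_MINUTES
    else:
        total_active = len(fixes) * interval_min
    foray_active = sum(s.active_duration_min for s in segments)
    pct = 100.0 * foray_active / total_active if total_active else 0.0
    return IndividualSummary(
        individual_id=deployment.individual_id,
        status=deployment.status,
        age=deployment.age,
        season=deployment.season,
        territory_size_km=territory_size_km,
        n_fixes=len(fixes),
        tracking_nights=n_nights,
        n_forays=n_forays,
        forays_per_week=per_week,
        pct_active_time_on_forays=pct,
    )


def segments_to_frame(segments: list[ForaySegment]) -> pd.DataFrame:
    """One row per foray, in the documented CSV column order."""
    cols = [
        "individual_id", "foray_index", "t_start", "t_end", "n_fixes",
        "duration_min", "active_duration_min", "distance_m", "n_territories",
        "spans_multiple_nights",
    ]
    rows = [{k: v for k, v in s.to_dict().items() if k in cols} for s in segments]
    return pd.DataFrame(rows, columns=cols)
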