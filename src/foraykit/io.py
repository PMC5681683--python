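"""Reading, validation and quality filtering of GPS fixes and landscapes.

Fixes travel through the pipeline as a pandas DataFrame with one row per
GPS record (columns: ``individual_id``, ``timestamp`` tz-aware, ``x``,
``y`` in metres, ``hdop``, ``n_satellites``, plus the derived labels
``medium`` and ``movement_type``).  Landscapes (river centerline, water
body, territory mosaic) are GeoJSON FeatureCollections in a planar metric
CRS.

Quality filtering follows the standard telemetry screen for this kind of
deployment: the capture night is discarded to remove handling effects, and
imprecise fixes (HDOP > 5, or fewer than 4 satellites) are dropped.  Both
thresholds are strict: HDOP = 5.0 with 4 satellites is retained.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape

from .stats import percent

log = logging.getLogger(__name__)

__all__ = [
    "FIX_COLUMNS",
    "DEFAULT_TZ",
    "FormatError",
    "Deployment",
    "Landscape",
    "FilterReport",
    "read_fixes",
    "write_fixes",
    "read_deployments",
    "write_deployments",
    "read_landscape",
    "write_landscape",
    "activity_window",
    "night_of",
    "quality_filter",
]

FIX_COLUMNS = ["individual_id", "timestamp", "x", "y", "hdop", "n_satellites"]
DEFAULT_TZ = "Europe/Oslo"

#: Activity window of the nocturnal study animal: fixes are scheduled
#: every 15 min from 19:00 to 07:00 local wall-clock time.
ACTIVITY_START = time(19, 0)
ACTIVITY_END = time(7, 0)

#: Quality thresholds (strict: a fix is removed only if hdop > 5 or
#: n_satellites < 4).
HDOP_MAX = 5.0
MIN_SATELLITES = 4


class FormatError(ValueError):
    """Malformed input file (missing column, missing landscape role, ...)."""


@dataclass
class Deployment:
    """One GPS deployment on one individual."""

    individual_id: str
    status: str  # "dominant" | "subordinate"
    age: float  # minimum age in years
    season: str  # "spring" | "autumn"
    capture_night: date
    n_fixes_raw: int = 0
    n_fixes_retained: int = 0

    def __post_init__(self):
        if self.status not in ("dominant", "subordinate"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.season not in ("spring", "autumn"):
            raise ValueError(f"unknown season {self.season!r}")
        if isinstance(self.capture_night, str):
            self.capture_night = date.fromisoformat(self.capture_night)


@dataclass
class Landscape:
    """River centerline, water polygon, and the territory mosaic."""

    centerline: LineString
    water: Polygon
    territories: dict[str, Polygon] = field(default_factory=dict)

    def neighbor_territories(self, focal_id: str | None) -> dict[str, Polygon]:
        """All territories except the focal individual's own."""
        return {k: v for k, v in self.territories.items() if k != focal_id}

    def validate(self) -> list[str]:
        """Return warnings for territory pairs overlapping >=10% of either."""
        msgs = []
        ids = sorted(self.territories)
        for i, a in enumerate(ids):
            pa = self.territories[a]
            if not pa.intersects(self.water):
                msgs.append(f"territory {a} does not touch the water polygon")
            for b in ids[i + 1:]:
                pb = self.territories[b]
                inter = pa.intersection(pb).area
                if inter >= 0.10 * min(pa.area, pb.area):
                    msgs.append(
                        f"territories {a} and {b} overlap "
                        f"{100 * inter / min(pa.area, pb.area):.1f}% (>=10%)"
                    )
        return msgs


@dataclass
class FilterReport:
    """Bookkeeping of the quality screen.

    A fix failing both the capture-night and the precision rule is counted
    once, under the precision (quality) rule, so the three counts always sum
    to the input size.
    """

    n_input: int
    removed_quality: int
    removed_capture_night: int
    n_retained: int

    @property
    def pct_removed(self) -> float:
        if self.n_input == 0:
            return 0.0
        return percent(self.removed_quality + self.removed_capture_night, self.n_input)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_quality": self.removed_quality,
            "removed_capture_night": self.removed_capture_night,
            "n_retained": self.n_retained,
            "pct_removed": self.pct_removed,
        }


# ---------------------------------------------------------------------------
# fixes


def read_fixes(path, tz: str = DEFAULT_TZ, on_bad_row: str = "fail") -> pd.DataFrame:
    """Read a GPS fix table from CSV.

    Parameters
    ----------
    path
        CSV with header columns ``individual_id, timestamp, x, y, hdop,
        n_satellites``; timestamps ISO-8601 (naive timestamps are localized
        to ``tz``).
    on_bad_row
        ``"fail"`` raises on the first unparseable row; ``"skip"`` drops bad
        rows with a logged warning carrying their line numbers.

    Returns a DataFrame sorted by (individual_id, timestamp).  Duplicate
    (individual, timestamp) records are an error.
    """
    if on_bad_row not in ("fail", "skip"):
        raise ValueError("on_bad_row must be 'fail' or 'skip'")
    df = pd.read_csv(path, dtype={"individual_id": str})
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    num = {c: pd.to_numeric(df[c], errors="coerce") for c in ("x", "y", "hdop", "n_satellites")}
    bad = ts.isna()
    for c in num:
        bad |= num[c].isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        if on_bad_row == "fail":
            raise FormatError(f"{path}: unparseable rows at lines {lines[:20]}")
        log.warning("%s: skipping %d bad rows (lines %s)", path, bad.sum(), lines[:20])
        df, ts = df[~bad], ts[~bad]
        num = {c: v[~bad] for c, v in num.items()}
    out = pd.DataFrame(
        {
            "individual_id": df["individual_id"].values,
            "timestamp": ts.dt.tz_convert(ZoneInfo(tz)).values,
            "x": num["x"].astype(float).values,
            "y": num["y"].astype(float).values,
            "hdop": num["hdop"].astype(float).values,
            "n_satellites": num["n_satellites"].astype(int).values,
        }
    )
    dup = out.duplicated(subset=["individual_id", "timestamp"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (individual, timestamp) records ({dup.sum()})")
    out = out.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(drop=True)
    for c in ("medium", "movement_type"):
        out[c] = "unset"
    return out


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write a fix table to CSV with ISO-8601 timestamps (zone offset kept)."""
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    cols = FIX_COLUMNS + [c for c in out.columns if c not in FIX_COLUMNS]
    out[cols].to_csv(path, index=False)


def read_deployments(path) -> list[Deployment]:
    df = pd.read_csv(path, dtype={"individual_id": str})
    required = ["individual_id", "status", "age", "season", "capture_night"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Deployment(
                individual_id=str(row.individual_id),
                status=row.status,
                age=float(row.age),
                season=row.season,
                capture_night=date.fromisoformat(str(row.capture_night)),
                n_fixes_raw=int(getattr(row, "n_fixes_raw", 0) or 0),
                n_fixes_retained=int(getattr(row, "n_fixes_retained", 0) or 0),
            )
        )
    return out


def write_deployments(deployments: list[Deployment], path) -> None:
    rows = [
        {
            "individual_id": d.individual_id,
            "status": d.status,
            "age": d.age,
            "season": d.season,
            "capture_night": d.capture_night.isoformat(),
            "n_fixes_raw": d.n_fixes_raw,
            "n_fixes_retained": d.n_fixes_retained,
        }
        for d in deployments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# landscape GeoJSON


def _round_coords(obj, ndigits=6):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, ndigits) for o in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def read_landscape(path) -> Landscape:
    """Read a landscape GeoJSON FeatureCollection.

    Expects one LineString feature with ``properties.role == "centerline"``,
    one Polygon with ``role == "water"``, and >=1 Polygon features carrying a
    ``territory_id`` property.  Territory overlap >=10% logs a warning but is
    not an error (field territories may overlap marginally).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: not a GeoJSON FeatureCollection")
    centerline = water = None
    territories: dict[str, Polygon] = {}
    for i, feat in enumerate(gj.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as e:  # corrupt feature
            raise FormatError(f"{path}: feature {i}: bad geometry ({e})") from e
        props = feat.get("properties") or {}
        role = props.get("role")
        if role == "centerline":
            centerline = geom
        elif role == "water":
            water = geom
        elif "territory_id" in props:
            territories[str(props["territory_id"])] = geom
    if centerline is None or water is None or not territories:
        raise FormatError(
            f"{path}: needs a centerline LineString, a water Polygon and >=1 territory"
        )
    ls = Landscape(centerline=centerline, water=water, territories=territories)
    for msg in ls.validate():
        log.warning("%s: %s", path, msg)
        warnings.warn(msg, stacklevel=2)
    return ls


def write_landscape(landscape: Landscape, path) -> None:
    """Write a landscape as deterministic GeoJSON (sorted keys, 6-decimal
    coordinates) so identical landscapes produce identical bytes."""
    features = [
        {
            "type": "Feature",
            "properties": {"role": "centerline"},
            "geometry": _round_coords(mapping(landscape.centerline)),
        },
        {
            "type": "Feature",
            "properties": {"role": "water"},
            "geometry": _round_coords(mapping(landscape.water)),
        },
    ]
    for tid in sorted(landscape.territories):
        features.append(
            {
                "type": "Feature",
                "properties": {"territory_id": tid},
                "geometry": _round_coords(mapping(landscape.territories[tid])),
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# activity window and quality filter


def activity_window(ts) -> bool:
    """True iff the local wall-clock time is in [19:00, 07:00), the animals'
    nightly activity window (crosses midnight)."""
    t = pd.Timestamp(ts).time()
    return t >= ACTIVITY_START or t < ACTIVITY_END


def night_of(ts) -> date:
    """Night index of a fix: the calendar date on which the activity window
    containing it started (a 00:15 fix belongs to the previous evening)."""
    ts = pd.Timestamp(ts)
    if ts.time() >= ACTIVITY_START:
        return ts.date()
    return (ts - timedelta(days=1)).date()


def quality_filter(
    fixes: pd.DataFrame, deployment: Deployment | None = None,
    hdop_max: float = HDOP_MAX, min_satellites: int = MIN_SATELLITES,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the telemetry quality screen.

    Removes (a) every fix in the capture night's activity window (19:00 on
    the capture date to 07:00 the next morning), (b) fixes with HDOP >
    ``hdop_max``, (c) fixes with fewer than ``min_satellites`` satellites.
    Thresholds are strict; a fix at HDOP 5.0 with 4 satellites survives.

    Returns the retained fixes (original order) and a :class:`FilterReport`.
    The filter is idempotent.
    """
    n = len(fixes)
    bad_quality = (fixes["hdop"].values > hdop_max) | (
        fixes["n_satellites"].values < min_satellites
    )
    in_capture = np.zeros(n, dtype=bool)
    if deployment is not None and n:
        tz = fixes["timestamp"].iloc[0].tzinfo
        start = pd.Timestamp(
            datetime.combine(deployment.capture_night, ACTIVITY_START), tz=tz
        )
        end = start + timedelta(hours=12)
        in_capture = (fixes["timestamp"] >= start).values & (fixes["timestamp"] < end).values
    removed_quality = int(bad_quality.sum())
    removed_capture = int((in_capture & ~bad_quality).sum())
    keep = ~(bad_quality | in_capture)
    retained = fixes[keep].reset_index(drop=True)
    report = FilterReport(
        n_input=n,
        removed_quality=removed_quality,
        removed_capture_night=removed_capture,
        n_retained=len(retained),
    )
    if deployment is not None:
        deployment.n_fixes_raw = n
        deployment.n_fixes_retained = len(retained)
    return retained, report
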