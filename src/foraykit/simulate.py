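"""Seeded simulator of a river landscape, a territory mosaic, and
shore-bound trajectories with planted forays and full ground-truth labels.

The generator exists so every pipeline stage can be exercised end to end
without field data.  It emulates the study design the pipeline targets:
15-min GPS fixes restricted to the 19:00-07:00 activity window, movement
confined to a narrow river corridor, adjacent non-overlapping territories
strung along the river, occasional forays penetrating one to five
neighbouring territories (sometimes laying up over the day and returning
the next night), Gaussian GPS noise, fix dropout, and a fraction of fixes
given disqualifying HDOP/satellite values.

The movement model is a shore-attracted correlated walk parametrised in
river coordinates (chainage along the centerline, lateral offset), not a
fit to real kinematics; only the properties the pipeline measures (speeds,
water proportions, foray geometry and timing) are controlled.  Truth
labels are recorded before noise is added.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import substring

from .io import (
    DEFAULT_TZ,
    Deployment,
    Landscape,
    write_deployments,
    write_fixes,
    write_landscape,
)

__all__ = [
    "IntraParams",
    "ForayParams",
    "SimulationConfig",
    "SimulatedLandscape",
    "Bundle",
    "simulate_landscape",
    "simulate_individual",
    "simulate_population",
    "default_statuses",
]


@dataclass
class IntraParams:
    """Within-territory movement: mostly in water, hugging the shore."""

    water_prob: float = 0.75
    speed_water_m_hr: float = 600.0
    speed_land_m_hr: float = 250.0
    #: mean perpendicular distance (m) of land excursions beyond the shore
    shore_attraction: float = 12.0


@dataclass
class ForayParams:
    """Planted extra-territorial excursions.

    Foray counts in the field are zero-heavy and overdispersed: many
    animals never leave their territory, and those that do differ in
    propensity.  The generator therefore mixes a structural never-forayer
    class (``p_never``) with gamma-distributed individual rate multipliers
    (``rate_shape``; mean 1), which makes the per-deployment counts
    genuinely zero-inflated negative-binomial.
    """

    p_per_night: float = 0.12
    p_never: float = 0.25
    rate_shape: float = 1.5
    #: P(intruding exactly 1..5 territories); truncated to the neighbours
    #: actually available in the chosen direction
    depth_weights: tuple[float, ...] = (0.60, 0.25, 0.08, 0.04, 0.03)
    speed_m_hr: float = 1400.0
    water_prob: float = 0.90
    p_multi_night: float = 0.08
    #: the deepest point of a foray lies at least this far (chainage m)
    #: beyond the home border, keeping planted fixes clear of the 100 m rule
    min_penetration_m: float = 300.0
    dwell_steps_max: int = 6


@dataclass
class SimulationConfig:
    """Everything the generator draws from; same seed, same bytes."""

    seed: int = 0
    n_territories: int = 8
    #: (min, max) km of bank length per territory, drawn uniformly; a
    #: scalar plants every territory at that exact length
    territory_length_km: float | tuple[float, float] = (1.0, 5.0)
    river_width_m: float = 40.0
    #: lateral land depth of territory polygons beyond the shore
    land_margin_m: float = 60.0
    end_margin_m: float = 500.0
    #: bearing-increment SD (radians per 50 m step) of the centerline walk
    bearing_sd: float = 0.06
    n_nights: int | None = None  # fixed nights per deployment; None -> draw
    nights_mean: float = 10.3
    nights_sd: float = 3.9
    nights_range: tuple[int, int] = (4, 22)
    fix_interval_min: int = 15
    gps_noise_sd_m: float = 5.0
    p_drop: float = 0.05
    hdop_bad_rate: float = 0.101
    tz: str = DEFAULT_TZ
    intra: IntraParams = field(default_factory=IntraParams)
    foray: ForayParams = field(default_factory=ForayParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "intra" in d and isinstance(d["intra"], dict):
            d["intra"] = IntraParams(**d["intra"])
        if "foray" in d and isinstance(d["foray"], dict):
            fo = dict(d["foray"])
            if "depth_weights" in fo:
                fo["depth_weights"] = tuple(fo["depth_weights"])
            d["foray"] = ForayParams(**fo)
        if "territory_length_km" in d and isinstance(d["territory_length_km"], list):
            d["territory_length_km"] = tuple(d["territory_length_km"])
        if "nights_range" in d and isinstance(d["nights_range"], list):
            d["nights_range"] = tuple(d["nights_range"])
        return cls(**d)


@dataclass
class SimulatedLandscape:
    """Landscape plus the chainage interval each territory occupies."""

    landscape: Landscape
    spans: dict[str, tuple[float, float]]
    lengths_km: dict[str, float]


@dataclass
class Bundle:
    """An in-memory simulated dataset (optionally written to disk)."""

    fixes: pd.DataFrame
    truth: pd.DataFrame
    deployments: list[Deployment]
    sim_landscape: SimulatedLandscape
    home_map: dict[tuple[str, str], str]  # (individual_id, season) -> territory_id
    config: SimulationConfig

    @property
    def landscape(self) -> Landscape:
        return self.sim_landscape.landscape


# ---------------------------------------------------------------------------
# landscape


def simulate_landscape(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedLandscape:
    """Sinuous centerline + buffered water body + adjacent territories.

    Territories are consecutive chainage intervals of the configured bank
    lengths, buffered laterally (flat caps), so adjacent polygons share a
    border but overlap only marginally on bends.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tl = config.territory_length_km
    if np.isscalar(tl):
        lengths = np.full(config.n_territories, float(tl) * 1000.0)
    else:
        lengths = rng.uniform(tl[0] * 1000.0, tl[1] * 1000.0, config.n_territories)
    total = float(lengths.sum()) + 2 * config.end_margin_m

    step = 50.0
    n_steps = int(np.ceil(total / step)) + 2
    bearings = np.cumsum(rng.normal(0.0, config.bearing_sd, n_steps))
    dx = step * np.cos(bearings)
    dy = step * np.sin(bearings)
    xs = np.concatenate([[0.0], np.cumsum(dx)])
    ys = np.concatenate([[0.0], np.cumsum(dy)])
    centerline = LineString(np.column_stack([xs, ys]))
    water = centerline.buffer(config.river_width_m / 2.0)

    half = config.river_width_m / 2.0 + config.land_margin_m
    spans: dict[str, tuple[float, float]] = {}
    lengths_km: dict[str, float] = {}
    territories: dict[str, Polygon] = {}
    s = config.end_margin_m
    for i, length in enumerate(lengths):
        tid = f"T{i + 1:02d}"
        seg = substring(centerline, s, s + length)
        poly = seg.buffer(half, cap_style="flat")
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        territories[tid] = poly
        spans[tid] = (s, s + length)
        lengths_km[tid] = length / 1000.0
        s += length
    landscape = Landscape(centerline=centerline, water=water, territories=territories)
    return SimulatedLandscape(landscape=landscape, spans=spans, lengths_km=lengths_km)


# ---------------------------------------------------------------------------
# individual trajectories


def _xy_at(line: LineString, s: float, d: float) -> tuple[float, float]:
    """Map river coordinates (chainage s, signed lateral offset d) to x/y."""
    L = line.length
    s = min(max(s, 0.0), L)
    p = line.interpolate(s)
    a = line.interpolate(max(s - 1.0, 0.0))
    b = line.interpolate(min(s + 1.0, L))
    tx, ty = b.x - a.x, b.y - a.y
    norm = float(np.hypot(tx, ty)) or 1.0
    return p.x - d * ty / norm, p.y + d * tx / norm


def _night_times(night: date, interval_min: int, tz: ZoneInfo) -> list[datetime]:
    start = datetime.combine(night, datetime.min.time(), tzinfo=tz) + timedelta(hours=19)
    n = int(12 * 60 / interval_min)
    return [start + timedelta(minutes=interval_min * i) for i in range(n)]


def simulate_individual(
    config: SimulationConfig,
    sim_landscape: SimulatedLandscape,
    deployment: Deployment,
    home_territory_id: str,
    n_nights: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One deployment's noisy fixes plus pre-noise truth labels.

    The animal performs a reflective correlated walk inside its home
    chainage interval (medium drawn per fix; land fixes offset beyond the
    shore).  On foray nights it travels along the river into ``k`` drawn
    neighbours at foray speed, dwells at the deepest point, and returns —
    or lays up over the day and returns the following night.  Truth
    movement/medium labels are evaluated geometrically on the pre-noise
    positions against the planted polygons.
    """
    land = sim_landscape.landscape
    line = land.centerline
    tz = ZoneInfo(config.tz)
    s0, s1 = sim_landscape.spans[home_territory_id]
    # animals patrol essentially to the border (scent mounds sit there)
    pad = min(20.0, (s1 - s0) / 20.0)
    fo = config.foray
    it = config.intra
    dt_hr = config.fix_interval_min / 60.0

    tids = sorted(sim_landscape.spans, key=lambda t: sim_landscape.spans[t][0])
    home_idx = tids.index(home_territory_id)
    up_neighbors = tids[home_idx + 1:]  # increasing chainage
    down_neighbors = tids[:home_idx][::-1]  # decreasing chainage

    # latent foray propensity of this deployment (structural zeros + gamma
    # heterogeneity make population counts zero-inflated and overdispersed)
    if rng.random() < fo.p_never:
        p_night = 0.0
    else:
        p_night = min(1.0, fo.p_per_night * rng.gamma(fo.rate_shape, 1.0 / fo.rate_shape))

    s = (s0 + s1) / 2.0
    direction = rng.choice([-1.0, 1.0])
    border_dwell = 0  # fixes left in a scent-marking stop at a border
    rows = []  # (timestamp, s, d, on_foray_excursion, foray_tag)
    layover = None  # (target_s, foray_tag) carried across the daytime
    foray_counter = 0

    nights = [deployment.capture_night + timedelta(days=k) for k in range(n_nights + 1)]
    for night_i, night in enumerate(nights):
        times = _night_times(night, config.fix_interval_min, tz)
        n_steps = len(times)
        plan = None
        if layover is not None:
            target_s, tag = layover
            dwell_left = int(rng.integers(1, fo.dwell_steps_max + 1))
            plan = ("return", target_s, tag, dwell_left)
            layover = None
        elif night_i > 0 and rng.random() < p_night:
            # plant a foray this night
            sides = []
            if up_neighbors:
                sides.append(+1)
            if down_neighbors:
                sides.append(-1)
            if sides:
                side = int(rng.choice(sides))
                avail = up_neighbors if side > 0 else down_neighbors
                w = np.asarray(fo.depth_weights[: len(avail)], dtype=float)
                k = int(rng.choice(np.arange(1, len(w) + 1), p=w / w.sum()))
                border = s1 if side > 0 else s0
                seg_lens = [
                    sim_landscape.spans[t][1] - sim_landscape.spans[t][0]
                    for t in avail[:k]
                ]
                depth = sum(seg_lens[:-1]) + rng.uniform(0.1, 0.5) * seg_lens[-1]
                depth = max(depth, fo.min_penetration_m)
                target_s = border + side * depth
                start_step = int(rng.integers(2, max(3, n_steps - 10)))
                multi = rng.random() < fo.p_multi_night and night_i < n_nights - 1
                foray_counter += 1
                tag = f"{deployment.individual_id}-f{foray_counter}"
                plan = ("out", target_s, tag, start_step, multi)

        mode = "intra"
        dwell = 0
        target_s = None
        tag = None
        if plan is not None and plan[0] == "return":
            mode = "dwell"
            _, target_s, tag, dwell = plan
            s = target_s

        for step_i, ts in enumerate(times):
            if plan is not None and plan[0] == "out" and step_i == plan[3]:
                mode = "travel_out"
                target_s, tag = plan[1], plan[2]
            step_scale = rng.uniform(0.6, 1.4)
            if mode == "intra":
                in_water = rng.random() < it.water_prob
                speed = it.speed_water_m_hr if in_water else it.speed_land_m_hr
                ds = speed * dt_hr * step_scale
                if border_dwell > 0:
                    # scent-marking stop: linger at the border just reached
                    border_dwell -= 1
                    s = float(np.clip(s + rng.uniform(-10.0, 10.0), s0 + pad, s1 - pad))
                elif not (s0 + pad <= s + direction * ds <= s1 - pad):
                    # reached a territory border: mark, dwell, turn around
                    s = s0 + pad if direction < 0 else s1 - pad
                    direction = -direction
                    border_dwell = int(rng.integers(1, 4))
                else:
                    s += direction * ds
                    # patrol-like persistence: occasional spontaneous turn
                    if rng.random() < 0.03:
                        direction = -direction
                d = (
                    rng.uniform(-0.4, 0.4) * config.river_width_m
                    if in_water
                    else (config.river_width_m / 2.0 + rng.exponential(it.shore_attraction))
                    * rng.choice([-1.0, 1.0])
                )
                on_foray = False
            else:
                in_water = rng.random() < fo.water_prob
                d = (
                    rng.uniform(-0.4, 0.4) * config.river_width_m
                    if in_water
                    else (config.river_width_m / 2.0 + rng.exponential(5.0))
                    * rng.choice([-1.0, 1.0])
                )
                ds = fo.speed_m_hr * dt_hr * step_scale
                if mode == "travel_out":
                    to_go = target_s - s
                    if abs(to_go) <= ds:
                        s = target_s
                        mode = "dwell"
                        dwell = int(rng.integers(1, fo.dwell_steps_max + 1))
                    else:
                        s += np.sign(to_go) * ds
                elif mode == "dwell":
                    s = target_s + rng.uniform(-30.0, 30.0)
                    dwell -= 1
                    if dwell <= 0:
                        if plan is not None and plan[0] == "out" and plan[4]:
                            # lay up over the day; return next night
                            layover = (target_s, tag)
                            mode = "layover"
                        else:
                            mode = "travel_back"
                elif mode == "layover":
                    s = target_s + rng.uniform(-30.0, 30.0)
                elif mode == "travel_back":
                    home_center = (s0 + s1) / 2.0
                    to_go = home_center - s
                    if abs(to_go) <= ds or s0 + pad <= s <= s1 - pad:
                        s = float(np.clip(s + np.sign(to_go) * min(abs(to_go), ds), s0 + pad, s1 - pad))
                        mode = "intra"
                    else:
                        s += np.sign(to_go) * ds
                on_foray = mode != "intra"
            d = float(np.clip(d, -(config.river_width_m / 2 + config.land_margin_m - 5),
                              config.river_width_m / 2 + config.land_margin_m - 5))
            rows.append((ts, s, d, on_foray, tag if on_foray else None))

    # river coords -> true planar coords
    xy = np.array([_xy_at(line, s_, d_) for _, s_, d_, _, _ in rows])
    pts = shapely.points(xy)
    home_poly = land.territories[home_territory_id]
    inside_home = shapely.covers(home_poly, pts)
    dist_border = shapely.distance(shapely.get_exterior_ring(home_poly), pts)
    in_neighbor = np.zeros(len(rows), dtype=bool)
    occupied = np.array([""] * len(rows), dtype=object)
    for tid in tids:
        cov = shapely.covers(land.territories[tid], pts)
        occupied[cov & (occupied == "")] = tid
        if tid != home_territory_id:
            in_neighbor |= cov
    truth_foray = (~inside_home) & (dist_border > 100.0) & in_neighbor
    truth_medium = np.where(shapely.covers(land.water, pts), "water", "land")

    timestamps = [r[0] for r in rows]
    tags = [r[4] if truth_foray[i] else None for i, r in enumerate(rows)]

    noisy = xy + rng.normal(0.0, config.gps_noise_sd_m, xy.shape)
    n = len(rows)
    bad = rng.random(n) < config.hdop_bad_rate
    bad_kind = rng.random(n) < 0.5
    hdop = np.round(rng.uniform(0.8, 4.9, n), 2)
    sats = rng.integers(4, 13, n)
    hdop[bad & bad_kind] = np.round(rng.uniform(5.5, 15.0, int((bad & bad_kind).sum())), 2)
    sats[bad & ~bad_kind] = rng.integers(0, 4, int((bad & ~bad_kind).sum()))
    keep = rng.random(n) >= config.p_drop

    fixes = pd.DataFrame(
        {
            "individual_id": deployment.individual_id,
            "timestamp": pd.to_datetime(timestamps),
            "x": noisy[:, 0],
            "y": noisy[:, 1],
            "hdop": hdop,
            "n_satellites": sats.astype(int),
        }
    )[keep].reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "individual_id": deployment.individual_id,
            "timestamp": pd.to_datetime(timestamps),
            "movement_type": np.where(truth_foray, "foray", "intra"),
            "medium": truth_medium,
            "foray_id": [t if t is not None else "" for t in tags],
            "territory_id": occupied,
            "true_x": xy[:, 0],
            "true_y": xy[:, 1],
        }
    )[keep].reset_index(drop=True)
    return fixes, truth


# ---------------------------------------------------------------------------
# population


def default_statuses() -> list[tuple[str, str]]:
    """The study design: 46 dominant + 10 subordinate deployments over 54
    unique individuals (two animals were tracked under both statuses)."""
    pairs = [(f"B{i:02d}", "dominant") for i in range(1, 47)]
    pairs += [(f"B{i:02d}", "subordinate") for i in range(45, 55)]
    return pairs


def _season_dates(season: str, rng: np.random.Generator) -> date:
    # windows chosen away from DST transitions
    if season == "spring":
        start, span = date(2014, 4, 5), 70
    else:
        start, span = date(2014, 8, 15), 60
    return start + timedelta(days=int(rng.integers(0, span)))


def simulate_population(
    config: SimulationConfig,
    statuses: list[tuple[str, str]] | None = None,
    out_dir=None,
) -> Bundle:
    """Simulate a full dataset bundle: landscape, deployments, fixes, truth.

    One deployment per (individual, status) pair; tracking length is drawn
    from a clipped normal (default mean 10.3, SD 3.9, range 4-22 nights).
    With ``out_dir`` the bundle is written atomically as ``fixes.csv``,
    ``landscape.geojson``, ``deployments.csv``, ``truth.csv`` and
    ``config.json``.
    """
    rng = np.random.default_rng(config.seed)
    sim_land = simulate_landscape(config, rng)
    tids = sorted(sim_land.spans)
    if statuses is None:
        statuses = default_statuses()

    deployments: list[Deployment] = []
    all_fixes, all_truth = [], []
    home_map: dict[tuple[str, str], str] = {}
    season_seen: dict[str, str] = {}
    for i, (iid, status) in enumerate(statuses):
        if iid in season_seen:
            # an individual tracked twice is tracked in the other season so
            # its two deployments occupy disjoint time windows
            season = "autumn" if season_seen[iid] == "spring" else "spring"
        else:
            season = "spring" if rng.random() < 0.5 else "autumn"
        season_seen[iid] = season
        age = float(rng.integers(2, 11)) if status == "dominant" else float(rng.integers(1, 5))
        dep = Deployment(
            individual_id=iid,
            status=status,
            age=age,
            season=season,
            capture_night=_season_dates(season, rng),
        )
        if config.n_nights is not None:
            n_nights = int(config.n_nights)
        else:
            lo, hi = config.nights_range
            n_nights = int(np.clip(round(rng.normal(config.nights_mean, config.nights_sd)), lo, hi))
        home = tids[i % len(tids)]
        home_map[(iid, season)] = home
        fixes, truth = simulate_individual(config, sim_land, dep, home, n_nights, rng)
        dep.n_fixes_raw = len(fixes)
        all_fixes.append(fixes)
        all_truth.append(truth)
        deployments.append(dep)

    fixes = pd.concat(all_fixes, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)
    # repeated deployments of one individual: keep records distinct in time
    fixes = fixes.drop_duplicates(subset=["individual_id", "timestamp"]).reset_index(drop=True)
    truth = truth.drop_duplicates(subset=["individual_id", "timestamp"]).reset_index(drop=True)
    bundle = Bundle(
        fixes=fixes, truth=truth, deployments=deployments,
        sim_landscape=sim_land, home_map=home_map, config=config,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: Bundle, out_dir) -> None:
    """Write the bundle atomically (tmp file + rename per output)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _atomic(name: str, writer) -> None:
        tmp = out / (name + ".tmp")
        writer(tmp)
        os.replace(tmp, out / name)

    _atomic("fixes.csv", lambda p: write_fixes(bundle.fixes, p))
    _atomic("landscape.geojson", lambda p: write_landscape(bundle.landscape, p))
    _atomic("deployments.csv", lambda p: write_deployments(bundle.deployments, p))

    def _write_truth(p):
        t = bundle.truth.copy()
        t["timestamp"] = t["timestamp"].map(lambda x: x.isoformat())
        t.to_csv(p, index=False)

    _atomic("truth.csv", _write_truth)
    _atomic(
        "config.json",
        lambda p: Path(p).write_text(json.dumps(bundle.config.to_dict(), sort_keys=True) + "\n"),
    )
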