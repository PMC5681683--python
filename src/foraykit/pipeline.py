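"""End-to-end orchestration: filter -> territories -> foray detection ->
movement metrics -> summaries -> count models -> averaged tables.

`run_all` is deterministic given (inputs, config): every output file, the
JSON/markdown report and the manifest (input hashes + config echo + output
hashes) depend only on them.  Logging goes to stderr and never into
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import forays as fr
from . import io as fio
from . import movement as mv
from . import stats as st
from . import territory as terr

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "process_deployment", "season_of_timestamp"]

#: covariates of the foray-count model
COUNT_COVARIATES = ("territory_size_km", "age", "season", "status", "n_gps_positions")
#: covariates of the movement-contrast models (per fix / per hourly record)
MOVEMENT_COVARIATES = ("movement_type", "age", "status", "season", "territory_size_km")
#: covariates of the per-foray models
FORAY_COVARIATES = ("age", "status", "season", "territory_size_km")


@dataclass
class PipelineConfig:
    """All pipeline constants in one serializable place."""

    fixes: str = "fixes.csv"
    landscape: str = "landscape.geojson"
    deployments: str = "deployments.csv"
    out_dir: str = "results"
    buffer_m: float = 100.0
    mcp_fraction: float = 0.95
    fix_interval_min: float = 15.0
    tz: str = fio.DEFAULT_TZ
    hdop_max: float = 5.0
    min_satellites: int = 4
    delta_aicc_max: float = 4.0
    max_gap_min: float = 20.0
    coverage: str = "scheduled"
    use_supplied_territories: bool = True
    on_bad_row: str = "fail"
    seed: int = 0
    fit_movement_models: bool = True
    fit_foray_models: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def season_of_timestamp(ts) -> str:
    """Deployment season of a fix (capture windows are disjoint by month:
    Jan-Jul spring, Aug-Dec autumn)."""
    return "spring" if pd.Timestamp(ts).month <= 7 else "autumn"


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def deployment_fixes(fixes: pd.DataFrame, dep: fio.Deployment) -> pd.DataFrame:
    """The fixes belonging to one deployment: the individual's fixes in the
    deployment's season window (an individual tracked under both statuses
    was tracked in different seasons)."""
    sub = fixes[fixes["individual_id"] == dep.individual_id]
    seasons = sub["timestamp"].map(season_of_timestamp)
    return sub[seasons == dep.season].reset_index(drop=True)


@dataclass
class DeploymentResult:
    deployment: fio.Deployment
    filter_report: fio.FilterReport
    fixes: pd.DataFrame  # retained, with medium + movement_type labels
    territory: terr.Territory | None
    home_tid: str | None
    segments: list
    summary: fr.IndividualSummary | None
    refine_iterations: int = 0
    refine_converged: bool = True


def process_deployment(
    dep: fio.Deployment,
    fixes: pd.DataFrame,
    landscape: fio.Landscape,
    config: PipelineConfig,
) -> DeploymentResult:
    """Filter, delineate/classify, segment and summarize one deployment."""
    raw = deployment_fixes(fixes, dep)
    retained, report = fio.quality_filter(
        raw, dep, hdop_max=config.hdop_max, min_satellites=config.min_satellites
    )
    if len(retained) < 3:
        return DeploymentResult(dep, report, retained, None, None, [], None)

    home_tid = terr.home_territory_id(retained, landscape)
    n_iter, converged = 0, True
    if config.use_supplied_territories and home_tid is not None:
        # field-confirmed borders: classify against the supplied polygon
        focal_poly = landscape.territories[home_tid]
        labels = fr.classify_fixes(
            retained, focal_poly,
            landscape.neighbor_territories(home_tid), config.buffer_m,
        )
        retained = retained.copy()
        retained["movement_type"] = labels
        # territory *size* still comes from the MCP of intra fixes
        intra = retained[retained["movement_type"] == "intra"]
        try:
            territory = terr.delineate(
                intra.drop(columns="movement_type"),
                landscape.centerline, config.mcp_fraction,
                territory_id=home_tid, owner_ids=[dep.individual_id],
            )
            territory = terr.Territory(
                territory_id=home_tid, polygon=focal_poly,
                bank_length_km=territory.bank_length_km,
                owner_ids=[dep.individual_id],
            )
        except Exception:
            territory = None
    else:
        territory, retained, n_iter, converged = terr.refine_with_forays(
            retained, landscape, dep.individual_id,
            fraction=config.mcp_fraction, buffer_m=config.buffer_m,
        )
        focal_poly = territory.polygon

    retained["medium"] = mv.classify_medium(retained, landscape.water)
    segments = fr.build_segments(
        retained, focal_poly, landscape, home_tid, config.fix_interval_min
    )
    summary = fr.summarize_individual(
        dep, segments, retained,
        territory_size_km=territory.bank_length_km if territory else float("nan"),
        interval_min=config.fix_interval_min, coverage=config.coverage,
    )
    return DeploymentResult(
        dep, report, retained, territory, home_tid, segments, summary,
        refine_iterations=n_iter, refine_converged=converged,
    )


# ---------------------------------------------------------------------------


def _fit_and_average(response, family, covariates, table, delta_max):
    specs = st.candidate_set(response, family, covariates)
    fits = st.fit_candidates(specs, table)
    ok = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not ok:
        return None, fits
    return st.model_average(ok, delta_max), fits


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole pipeline and write results + manifest.

    Returns the report dictionary (also written as ``report.json`` and
    ``report.md`` under ``config.out_dir``).
    """
    t0 = _time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-12s %6.1fs", name, _time.time() - t0)

    fixes = fio.read_fixes(config.fixes, tz=config.tz, on_bad_row=config.on_bad_row)
    landscape = fio.read_landscape(config.landscape)
    deployments = fio.read_deployments(config.deployments)
    stage("read")

    results: list[DeploymentResult] = []
    for dep in deployments:
        results.append(process_deployment(dep, fixes, landscape, config))
    stage("deployments")

    # ---- assemble output tables
    labeled = pd.concat(
        [r.fixes for r in results if len(r.fixes)], ignore_index=True
    )
    seg_frames = []
    for r in results:
        if r.segments:
            f = fr.segments_to_frame(r.segments)
            f.insert(1, "status", r.deployment.status)
            f.insert(2, "season", r.deployment.season)
            seg_frames.append(f)
    forays_table = (
        pd.concat(seg_frames, ignore_index=True)
        if seg_frames
        else fr.segments_to_frame([])
    )
    summaries = pd.DataFrame(
        [r.summary.to_dict() for r in results if r.summary is not None]
    )
    summaries["n_gps_positions"] = summaries["n_fixes"]
    stage("tables")

    # ---- movement metrics
    speed_rows = []
    per_individual_movement = []
    for r in results:
        if r.summary is None:
            continue
        for movement_type, media in (("intra", "water_only"), ("foray", "all")):
            recs = mv.travel_speed(
                r.fixes, movement_type, media_used=media,
                max_gap_min=config.max_gap_min,
            )
            for rec in recs:
                d = rec.to_dict()
                d.update(status=r.deployment.status, season=r.deployment.season,
                         age=r.deployment.age,
                         territory_size_km=r.summary.territory_size_km)
                speed_rows.append(d)
        for movement_type in ("intra", "foray"):
            sub = r.fixes[r.fixes["movement_type"] == movement_type]
            if len(sub):
                per_individual_movement.append(
                    {
                        "individual_id": r.deployment.individual_id,
                        "movement_type": movement_type,
                        "prop_water": mv.proportion_in_water(sub),
                        "n_fixes": len(sub),
                    }
                )
    speeds = pd.DataFrame(speed_rows)
    stage("movement")

    # ---- descriptive report
    n_dep = len([r for r in results if r.summary is not None])
    foraying = summaries[summaries["n_forays"] > 0]
    dom = summaries[summaries["status"] == "dominant"]
    sub = summaries[summaries["status"] == "subordinate"]
    filter_tot = {
        "n_input": sum(r.filter_report.n_input for r in results),
        "removed_quality": sum(r.filter_report.removed_quality for r in results),
        "removed_capture_night": sum(r.filter_report.removed_capture_night for r in results),
        "n_retained": sum(r.filter_report.n_retained for r in results),
    }
    filter_tot["pct_removed_quality"] = (
        st.percent(filter_tot["removed_quality"], filter_tot["n_input"])
        if filter_tot["n_input"] else 0.0
    )

    def _pct(num, den):
        return st.percent(num, den) if den else 0.0

    report = {
        "n_deployments": n_dep,
        "filter": filter_tot,
        "pct_individuals_with_forays": _pct(len(foraying), n_dep),
        "pct_dominant_with_forays": _pct(int((dom["n_forays"] > 0).sum()), len(dom)),
        "pct_subordinate_with_forays": _pct(int((sub["n_forays"] > 0).sum()), len(sub)),
        "n_forays_total": int(summaries["n_forays"].sum()),
        "forays_per_individual": st.describe(summaries["n_forays"]).to_dict()
        if n_dep else {},
        "forays_per_week": st.describe(summaries["forays_per_week"]).to_dict()
        if n_dep else {},
        "pct_active_time": st.describe(summaries["pct_active_time_on_forays"]).to_dict()
        if n_dep else {},
        "foray_duration_hr": st.describe(forays_table["active_duration_min"] / 60.0).to_dict()
        if len(forays_table) else {},
        "foray_distance_m": st.describe(forays_table["distance_m"]).to_dict()
        if len(forays_table) else {},
        "territories_intruded": st.describe(forays_table["n_territories"]).to_dict()
        if len(forays_table) else {},
        "multi_night_forays": int(forays_table["spans_multiple_nights"].sum())
        if len(forays_table) else 0,
    }

    # foray-metric intercorrelation (distance, duration, intrusions)
    if len(forays_table) >= 3:
        try:
            report["foray_metric_correlations"] = {
                "distance_duration": st.pearson_r(
                    forays_table["distance_m"], forays_table["duration_min"]
                ),
                "distance_intrusions": st.pearson_r(
                    forays_table["distance_m"], forays_table["n_territories"]
                ),
                "duration_intrusions": st.pearson_r(
                    forays_table["duration_min"], forays_table["n_territories"]
                ),
            }
        except ValueError:
            pass
    stage("describe")

    # ---- inference
    model_tables: dict[str, dict] = {}
    if n_dep >= 10:
        screen = st.collinearity_screen(summaries, COUNT_COVARIATES)
        report["collinearity_flagged"] = [
            {"a": a, "b": b, "r": r} for a, b, r in screen["flagged"]
        ]
        avg, fits = _fit_and_average(
            "n_forays", "zinb", COUNT_COVARIATES, summaries, config.delta_aicc_max
        )
        if avg is not None:
            model_tables["n_forays_zinb"] = {
                "table": avg.table().to_dict(orient="records"),
                "n_candidates": len(fits),
                "n_converged": sum(f.converged for f in fits),
                "n_retained": len(avg.retained),
                "weights": avg.weights,
            }
    if config.fit_movement_models and len(forays_table) and n_dep:
        fix_rows = labeled.merge(
            summaries[["individual_id", "status", "season", "age", "territory_size_km"]],
            on="individual_id", how="inner",
        )
        # the movement contrast uses only individuals that made forays
        movers = set(foraying["individual_id"])
        fix_rows = fix_rows[fix_rows["individual_id"].isin(movers)].reset_index(drop=True)
        if len(fix_rows) >= 50 and fix_rows["movement_type"].nunique() == 2:
            fix_rows["in_water"] = (fix_rows["medium"] == "water").astype(float)
            avg, fits = _fit_and_average(
                "in_water", "bernoulli_logit", MOVEMENT_COVARIATES,
                fix_rows, config.delta_aicc_max,
            )
            if avg is not None:
                model_tables["prop_water_logit"] = {
                    "table": avg.table().to_dict(orient="records"),
                    "n_retained": len(avg.retained),
                }
        if len(speeds) >= 50 and speeds["movement_type"].nunique() == 2:
            avg, fits = _fit_and_average(
                "speed_m_per_hr", "gaussian_identity", MOVEMENT_COVARIATES,
                speeds, config.delta_aicc_max,
            )
            if avg is not None:
                model_tables["travel_speed_lm"] = {
                    "table": avg.table().to_dict(orient="records"),
                    "n_retained": len(avg.retained),
                }
    if config.fit_foray_models and len(forays_table) >= 15:
        foray_cov = forays_table.merge(
            summaries[["individual_id", "age", "territory_size_km"]],
            on="individual_id", how="left",
        )
        for resp, fam, key in (
            ("distance_m", "gaussian_identity", "foray_distance_lm"),
            ("duration_min", "gaussian_identity", "foray_duration_lm"),
            ("n_territories", "poisson_log", "intrusions_poisson"),
        ):
            avg, fits = _fit_and_average(
                resp, fam, FORAY_COVARIATES, foray_cov, config.delta_aicc_max
            )
            if avg is not None:
                model_tables[key] = {
                    "table": avg.table().to_dict(orient="records"),
                    "n_retained": len(avg.retained),
                }
    report["model_tables"] = model_tables
    stage("models")

    # ---- write outputs
    fio.write_fixes(labeled, out / "fixes_labeled.csv")
    forays_table.to_csv(out / "forays.csv", index=False)
    summaries.to_csv(out / "summaries.csv", index=False)
    speeds.to_csv(out / "speeds.csv", index=False)
    if per_individual_movement:
        pd.DataFrame(per_individual_movement).to_csv(
            out / "movement_by_individual.csv", index=False
        )
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=_json_default) + "\n"
    )
    (out / "report.md").write_text(render_report_md(report))

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("fixes", "landscape", "deployments")
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name not in ("manifest.json",) and p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    stage("write")
    return report


def _fmt_desc(d: dict, nd: int = 2, unit: str = "") -> str:
    if not d:
        return "n/a"
    r = st.round_half_up
    return (
        f"mean ± SD: {r(d['mean'], nd)} ± {r(d['sd'], nd)}{unit}, "
        f"median: {r(d['median'], nd)}{unit}, "
        f"range: {r(d['min'], nd)}–{r(d['max'], nd)}{unit}"
    )


def render_report_md(report: dict) -> str:
    """Results-style markdown summary of a pipeline run."""
    lines = ["# Foray analysis report", ""]
    f = report["filter"]
    lines += [
        f"GPS deployments analysed: {report['n_deployments']}.",
        f"Quality screen: {f['removed_quality']} of {f['n_input']} positions removed "
        f"({f.get('pct_removed_quality', 0.0)}%) for HDOP/satellite limits; "
        f"{f['removed_capture_night']} capture-night positions excluded; "
        f"{f['n_retained']} retained.",
        "",
        f"Individuals with ≥1 foray: {report['pct_individuals_with_forays']}% "
        f"(dominants {report['pct_dominant_with_forays']}%, "
        f"subordinates {report['pct_subordinate_with_forays']}%).",
        f"Total forays: {report['n_forays_total']} "
        f"({report['multi_night_forays']} spanning more than one night).",
        "",
        f"- Forays per individual — {_fmt_desc(report['forays_per_individual'])}",
        f"- Forays per week — {_fmt_desc(report['forays_per_week'])}",
        f"- % active time on forays — {_fmt_desc(report['pct_active_time'])}",
        f"- Foray duration (active hrs) — {_fmt_desc(report['foray_duration_hr'])}",
        f"- Foray distance (m) — {_fmt_desc(report['foray_distance_m'])}",
        f"- Territories intruded — {_fmt_desc(report['territories_intruded'])}",
        "",
    ]
    for name, tbl in report.get("model_tables", {}).items():
        lines.append(f"## Model-averaged coefficients: {name}")
        lines.append("")
        lines.append("| Variable | β | SE | LCI | UCI | informative |")
        lines.append("|---|---|---|---|---|---|")
        for row in tbl["table"]:
            lines.append(
                f"| {row['Variable']} | {row['beta']} | {row['SE']} | "
                f"{row['LCI']} | {row['UCI']} | {row['informative']} |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
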