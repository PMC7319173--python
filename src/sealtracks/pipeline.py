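"""Orchestration: input validation and the end-to-end run.

``run_pipeline`` executes prefilter -> CTCRW fit -> 6-hr prediction ->
habitat annotation -> behavior segmentation -> monthly budgets on on-disk
inputs, logging per-stage record counts and writing every stage's output
plus a run manifest (config + counts) so each reported number traces to a
stage file.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import budget as budget_mod
from . import divebehavior as db
from . import habitat as hab
from . import rasters, track
from .config import AnalysisConfig

log = logging.getLogger("sealtracks")

FIX_COLUMNS = ["seal_id", "timestamp", "lon", "lat", "lc"]
DIVE_COLUMNS = ["seal_id", "start", "end", "max_depth_m"]
DRY_COLUMNS = ["seal_id", "date", "hour", "percent_dry"]


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: dict) -> list[str]:
    """Schema/sanity report for the pipeline inputs; empty list = clean.

    Checks column sets, timestamp parse and per-seal monotonicity,
    coordinate ranges, percent-dry ranges, and raster georeferencing.
    """
    violations: list[str] = []

    def check_csv(name, required):
        p = paths.get(name)
        if p is None:
            return None
        p = pathlib.Path(p)
        if not p.exists():
            violations.append(f"{name}: file not found: {p}")
            return None
        df = pd.read_csv(p)
        missing = set(required) - set(df.columns)
        if missing:
            violations.append(f"{name}: missing columns {sorted(missing)}")
            return None
        return df

    fixes = check_csv("fixes", FIX_COLUMNS)
    if fixes is not None:
        ts = pd.to_datetime(fixes["timestamp"], errors="coerce")
        for i in np.flatnonzero(ts.isna().values)[:5]:
            violations.append(f"fixes: row {i}: unparseable timestamp field 'timestamp'")
        bad_lat = np.flatnonzero(~fixes["lat"].between(-90, 90).values)
        for i in bad_lat[:5]:
            violations.append(f"fixes: row {i}: field 'lat' out of range: {fixes['lat'].iloc[i]}")
        bad_lon = np.flatnonzero(~fixes["lon"].between(-180, 360).values)
        for i in bad_lon[:5]:
            violations.append(f"fixes: row {i}: field 'lon' out of range: {fixes['lon'].iloc[i]}")
        for sid, grp in fixes.assign(_ts=ts).groupby("seal_id"):
            t = grp["_ts"].dropna()
            if not t.is_monotonic_increasing:
                violations.append(f"fixes: seal {sid}: timestamps not sorted ascending")

    dives = check_csv("dives", DIVE_COLUMNS)
    if dives is not None:
        s = pd.to_datetime(dives["start"], errors="coerce")
        e = pd.to_datetime(dives["end"], errors="coerce")
        for i in np.flatnonzero((e <= s).values)[:5]:
            violations.append(f"dives: row {i}: field 'end' not after 'start'")
        for i in np.flatnonzero(~(dives["max_depth_m"] > 0).values)[:5]:
            violations.append(f"dives: row {i}: field 'max_depth_m' not positive")

    dry = check_csv("drytimes", DRY_COLUMNS)
    if dry is not None:
        for i in np.flatnonzero(~dry["hour"].between(0, 23).values)[:5]:
            violations.append(f"drytimes: row {i}: field 'hour' out of range")
        for i in np.flatnonzero(~dry["percent_dry"].between(0, 100).values)[:5]:
            violations.append(f"drytimes: row {i}: field 'percent_dry' out of range")

    for name in ("bathymetry", "ice"):
        p = paths.get(name)
        if p is None:
            continue
        p = pathlib.Path(p)
        if not p.exists():
            violations.append(f"{name}: file not found: {p}")
            continue
        ds = rasters.open_netcdf(p)
        for attr in ("center_lon", "center_lat", "cell_km"):
            if attr not in ds.attrs:
                violations.append(f"{name}: missing georeferencing attribute '{attr}'")
    return violations


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _read_inputs(paths: dict):
    fixes = pd.read_csv(paths["fixes"], parse_dates=["timestamp"])
    dives = pd.read_csv(paths["dives"], parse_dates=["start", "end"])
    dry = pd.read_csv(paths["drytimes"], parse_dates=["date"])
    coverage = None
    if paths.get("coverage") and pathlib.Path(paths["coverage"]).exists():
        coverage = pd.read_csv(paths["coverage"], parse_dates=["start", "end"])
    bathy = rasters.open_netcdf(paths["bathymetry"])
    ice = rasters.open_netcdf(paths["ice"]) if paths.get("ice") else None
    return fixes, dives, dry, coverage, bathy, ice


def _drop_first_week(fixes, dives, dry):
    """Remove the first post-deployment week of behavior data per seal."""
    out = []
    for df, tcol in ((dives, "start"), (dry, None)):
        parts = []
        for sid, grp in df.groupby("seal_id", sort=True):
            if tcol is None:
                t = pd.to_datetime(grp["date"]) + pd.to_timedelta(grp["hour"], unit="h")
            else:
                t = grp[tcol]
            t0 = fixes.loc[fixes["seal_id"] == sid, "timestamp"].min()
            if pd.isna(t0):
                t0 = t.min()
            parts.append(grp[t >= t0 + pd.Timedelta(days=7)])
        out.append(pd.concat(parts, ignore_index=True) if parts else df)
    return out[0], out[1]


def run_pipeline(paths: dict, outdir, config: AnalysisConfig | None = None) -> dict:
    """Run every stage on the given inputs; returns the run manifest.

    ``paths`` maps input names (fixes, dives, drytimes, coverage,
    bathymetry, ice) to files; outputs and ``manifest.json`` are written to
    ``outdir``. Fails fast (before writing anything) on invalid inputs or a
    missing raster.
    """
    config = config or AnalysisConfig()
    out = pathlib.Path(outdir)

    violations = validate_inputs(paths)
    fatal = [v for v in violations if "not found" in v or "missing columns" in v]
    if fatal:
        raise InputError("; ".join(fatal))
    if "bathymetry" not in paths or not pathlib.Path(paths["bathymetry"]).exists():
        raise InputError("bathymetry raster is required")

    fixes, dives, dry, coverage, bathy, ice = _read_inputs(paths)
    out.mkdir(parents=True, exist_ok=True)
    counts = {"fixes_in": len(fixes), "dives_in": len(dives), "dry_hours_in": len(dry)}

    if config.first_week_excluded:
        dives, dry = _drop_first_week(fixes, dives, dry)
    counts["dives_after_first_week"] = len(dives)

    # track stage
    proj = rasters.grid_projection(bathy)
    retained, rejlog = track.prefilter_fixes(
        fixes, land_mask=bathy, max_speed=config.max_speed,
        spike_angle=config.spike_angle, spike_speed=config.spike_speed,
    )
    counts["fixes_retained"] = len(retained)
    counts["fixes_rejected"] = {r: int(n) for r, n in rejlog["reason"].value_counts().items()}
    estimates = []
    dropped = 0
    for sid, grp in retained.groupby("seal_id", sort=True):
        params = track.fit_ctcrw(grp, proj=proj)
        est, nd = track.predict_track(params, grp, proj, config.grid_step, config.se_max)
        estimates.append(est)
        dropped += nd
        log.info("seal %s: beta=%.3f sigma=%.3f loglik=%.1f, %d estimates (%d dropped)",
                 sid, params.beta, params.sigma, params.loglik, len(est), nd)
    estimates = pd.concat(estimates, ignore_index=True)
    counts["track_estimates"] = len(estimates)
    counts["track_estimates_dropped_se"] = dropped
    daily = track.daily_summaries(estimates)

    # habitat stage
    habitat_days = hab.annotate_track(
        estimates, bathy, ice, config.ice_radius, config.ice_edge_conc,
        config.ice_edge_min_pixels,
    )
    counts["habitat_days"] = len(habitat_days)
    counts["zone_days"] = {z: int(n) for z, n in habitat_days["zone"].value_counts().items()}

    # behavior stage
    flags, bouts = db.classify_haulout_hours(dry, config.dry_threshold)
    surfaces = db.derive_surface_intervals(dives, flags)
    episodes = db.segment_behavior(
        dives, surfaces, config.rest_surface_min, config.rep_tol,
        config.rep_min_dives, config.min_denom_depth,
    )
    episodes = db.flag_resting_overlaps(episodes, flags)
    labeled = db.label_dives(dives, episodes)
    depth_by_day = habitat_days.set_index(["seal_id", "date"])["ocean_depth_m"]
    key = pd.MultiIndex.from_arrays([labeled["seal_id"], labeled["start"].dt.normalize()])
    ocean = depth_by_day.reindex(key).values
    labeled["ocean_depth_m"] = ocean
    labeled["bottom_class"] = db.classify_bottom_dive(
        labeled["max_depth_m"].values, ocean, config.bottom_frac,
        config.min_bottom_ocean_depth,
    )
    counts["episodes"] = {k: int(n) for k, n in episodes["klass"].value_counts().items()}
    forays = hab.detect_forays(habitat_days, flags, config.bridge_break_days)
    counts["forays"] = len(forays)

    # budget stage
    if coverage is None:
        coverage = pd.DataFrame(columns=["seal_id", "start", "end"])
    budgets = budget_mod.monthly_budgets(
        flags, episodes, coverage, habitat_days,
        sample_min=config.sample_min, coast_excl_km=config.coast_excl,
    )
    counts["seal_months"] = len(budgets)
    counts["seal_months_included"] = int((~budgets["excluded"].astype(bool)).sum())
    try:
        table = budget_mod.budget_table(budgets)
    except ValueError:
        table = pd.DataFrame()

    outputs = {
        "estimates": out / "track_estimates.csv",
        "rejections": out / "fix_rejections.csv",
        "daily": out / "daily_summaries.csv",
        "habitat": out / "habitat_days.csv",
        "episodes": out / "episodes.csv",
        "dives_labeled": out / "dives_labeled.csv",
        "haulout_bouts": out / "haulout_bouts.csv",
        "forays": out / "forays.csv",
        "budgets": out / "budgets.csv",
        "budget_table": out / "budget_table.csv",
    }
    estimates.to_csv(outputs["estimates"], index=False)
    rejlog.to_csv(outputs["rejections"], index=False)
    daily.to_csv(outputs["daily"], index=False)
    habitat_days.to_csv(outputs["habitat"], index=False)
    episodes.to_csv(outputs["episodes"], index=False)
    labeled.to_csv(outputs["dives_labeled"], index=False)
    bouts.to_csv(outputs["haulout_bouts"], index=False)
    forays.to_csv(outputs["forays"], index=False)
    budgets.to_csv(outputs["budgets"], index=False)
    table.to_csv(outputs["budget_table"], index=False)

    manifest = {
        "config": config.to_dict(),
        "inputs": {k: str(v) for k, v in paths.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
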