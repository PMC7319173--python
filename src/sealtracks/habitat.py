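"""Daily habitat annotation: bathymetry, coast distance, sea-ice metrics,
depth zones, and off-shelf foray detection.

All point-to-cell distances are great-circle distances between the query
point and raster cell centers. Depth zones follow the shelf / shelf-break /
basin partition at 300 m and 1,000 m; the 300-1,000 m band is tracked but
excluded from dive-behavior analyses downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import rasters
from .projection import haversine_km

LAND = "land"


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def sample_depth(bathymetry: xr.Dataset, x_km: float, y_km: float):
    """Nearest-cell ocean depth (m); the string ``'land'`` over land."""
    if not rasters.point_in_grid(bathymetry, x_km, y_km):
        raise ValueError("point outside the bathymetry raster")
    iy, ix = rasters.nearest_cell_index(bathymetry, x_km, y_km)
    if bool(bathymetry["land"].values[iy, ix]):
        return LAND
    return float(bathymetry["depth"].values[iy, ix])


def _mainland_mask(bathymetry: xr.Dataset) -> np.ndarray:
    """Largest 8-connected land component (islands excluded)."""
    land = bathymetry["land"].values.astype(bool)
    lab, n = ndimage.label(land, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("raster contains no land")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def distance_to_mainland(bathymetry: xr.Dataset, lon: float, lat: float,
                         mainland: np.ndarray | None = None) -> float:
    """Great-circle km to the nearest mainland cell center; 0 on mainland."""
    if mainland is None:
        mainland = _mainland_mask(bathymetry)
    proj = rasters.grid_projection(bathymetry)
    x, y = proj.forward(lon, lat)
    iy, ix = rasters.nearest_cell_index(bathymetry, float(x), float(y))
    if mainland[iy, ix]:
        return 0.0
    d = haversine_km(lon, lat, bathymetry["lon"].values[mainland], bathymetry["lat"].values[mainland])
    return float(np.min(d))


def mean_ice_concentration(ice_field: xr.Dataset | xr.DataArray, lon: float, lat: float,
                           radius_km: float = 50.0) -> float:
    """Unweighted mean concentration over sea cells within the radius.

    ``ice_field`` is a single-day field (2-D ``ice_conc``). Returns NaN when
    every cell in the disc is land.
    """
    conc = ice_field["ice_conc"] if isinstance(ice_field, xr.Dataset) else ice_field
    if "time" in conc.dims:
        raise ValueError("pass a single-day ice field")
    base = ice_field if isinstance(ice_field, xr.Dataset) else ice_field.to_dataset(name="ice_conc")
    d = haversine_km(lon, lat, base["lon"].values, base["lat"].values)
    vals = conc.values
    sel = (d <= radius_km) & np.isfinite(vals)
    if not sel.any():
        return np.nan
    return float(vals[sel].mean())


def qualifying_ice_components(ice_field: xr.Dataset, conc_min: float = 15.0,
                              min_pixels: int = 10):
    """Label 8-connected ice components >= conc_min with >= min_pixels cells.

    Returns ``(labels, qualifying_ids, periphery_mask)``. A periphery cell
    is a qualifying-ice cell with at least one 8-neighbor that is sea but
    not qualifying ice (land and the grid border do not create periphery).
    """
    conc = ice_field["ice_conc"]
    if "time" in conc.dims:
        raise ValueError("pass a single-day ice field")
    vals = conc.values
    land = ~np.isfinite(vals)
    icy = np.isfinite(vals) & (vals >= conc_min)
    lab, n = ndimage.label(icy, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return lab, set(), np.zeros_like(icy)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    good = {i + 1 for i, s in enumerate(sizes) if s >= min_pixels}
    qual = np.isin(lab, list(good)) if good else np.zeros_like(icy)
    open_sea = ~qual & ~land
    nbr_sea = ndimage.maximum_filter(open_sea.astype(np.int8), size=3, mode="constant", cval=0)
    periph = qual & (nbr_sea > 0)
    return lab, good, periph


def distance_to_ice_edge(ice_field: xr.Dataset, lon: float, lat: float,
                         conc_min: float = 15.0, min_pixels: int = 10) -> float:
    """Signed great-circle km to the nearest qualifying ice periphery.

    Negative when the point's cell lies inside a qualifying component
    (inside the pack ice), positive outside; NaN when no qualifying ice
    exists anywhere in the field.
    """
    lab, good, periph = qualifying_ice_components(ice_field, conc_min, min_pixels)
    if not good or not periph.any():
        return np.nan
    proj = rasters.grid_projection(ice_field)
    x, y = proj.forward(lon, lat)
    iy, ix = rasters.nearest_cell_index(ice_field, float(x), float(y))
    inside = lab[iy, ix] in good
    d = haversine_km(lon, lat, ice_field["lon"].values[periph], ice_field["lat"].values[periph])
    dist = float(np.min(d))
    return -dist if inside else dist


def classify_zone(ocean_depth_m: float, shelf_max_m: float = 300.0,
                  basin_min_m: float = 1000.0) -> str:
    """shelf (< 300 m), break ([300, 1000] m), or basin (> 1000 m)."""
    if not np.isfinite(ocean_depth_m) or ocean_depth_m <= 0:
        raise ValueError("ocean depth must be positive")
    if ocean_depth_m < shelf_max_m:
        return "shelf"
    if ocean_depth_m <= basin_min_m:
        return "break"
    return "basin"


# ---------------------------------------------------------------------------
# daily annotation
# ---------------------------------------------------------------------------

def annotate_track(track: pd.DataFrame, bathymetry: xr.Dataset, ice: xr.Dataset | None = None,
                   ice_radius_km: float = 50.0, conc_min: float = 15.0,
                   min_pixels: int = 10) -> pd.DataFrame:
    """Per-seal-day habitat table from 6-hr track estimates.

    Each day is annotated at the estimate nearest 12:00 UTC: ocean depth,
    distance to mainland, 50-km mean ice concentration, signed ice-edge
    distance, and depth zone. Days whose midday position falls on a land
    cell carry NaN depth and zone ``'land'``.
    """
    mainland = _mainland_mask(bathymetry)
    rows = []
    for sid, grp in track.groupby("seal_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        for day, sub in grp.groupby(grp["timestamp"].dt.normalize()):
            midday = day + pd.Timedelta(hours=12)
            r = sub.loc[(sub["timestamp"] - midday).abs().idxmin()]
            depth = sample_depth(bathymetry, r["x_km"], r["y_km"])
            if depth == LAND:
                depth_v, zone = np.nan, "land"
            else:
                depth_v, zone = depth, classify_zone(depth)
            dml = distance_to_mainland(bathymetry, r["lon"], r["lat"], mainland)
            ice_c, ice_d = np.nan, np.nan
            if ice is not None:
                times = pd.DatetimeIndex(ice["time"].values)
                if day in times:
                    field = ice.sel(time=day)
                    ice_c = mean_ice_concentration(field, r["lon"], r["lat"], ice_radius_km)
                    ice_d = distance_to_ice_edge(field, r["lon"], r["lat"], conc_min, min_pixels)
            rows.append((sid, day, depth_v, dml, ice_c, ice_d, zone,
                         r["lon"], r["lat"], r["x_km"], r["y_km"]))
    return pd.DataFrame(
        rows,
        columns=["seal_id", "date", "ocean_depth_m", "dist_mainland_km",
                 "ice_conc_mean", "dist_ice_edge_km", "zone", "lon", "lat", "x_km", "y_km"],
    )


# ---------------------------------------------------------------------------
# forays
# ---------------------------------------------------------------------------

def detect_forays(habitat_days: pd.DataFrame, haulout_flags: pd.DataFrame | None = None,
                  bridge_break_days: int = 1) -> pd.DataFrame:
    """Maximal runs of consecutive basin days, bridging isolated break days.

    Up to ``bridge_break_days`` consecutive break-zone days sandwiched
    between basin days join the run (shelf-break transit does not split an
    off-shelf occupancy); shelf or missing days end it. Haul-out hours on
    member days are attached when flags are given.
    """
    forays = []
    for sid, grp in habitat_days.groupby("seal_id", sort=True):
        grp = grp.sort_values("date", kind="stable").reset_index(drop=True)
        dates = grp["date"].reset_index(drop=True)
        zones = grp["zone"].reset_index(drop=True)
        member_days: list[pd.Timestamp] = []
        pending_break: list[pd.Timestamp] = []

        def close():
            nonlocal member_days, pending_break
            if member_days:
                start, end = member_days[0], member_days[-1]
                depth = grp.loc[grp["date"].isin(member_days), "ocean_depth_m"].max()
                ho = 0.0
                if haulout_flags is not None:
                    f = haulout_flags[(haulout_flags["seal_id"] == sid) & haulout_flags["haulout"]]
                    ho = float(f["hour_start"].dt.normalize().isin(member_days).sum())
                forays.append((sid, start, end, (end - start).days + 1, float(depth), ho))
            member_days, pending_break = [], []

        prev_date = None
        for date, zone in zip(dates, zones):
            contiguous = prev_date is not None and (date - prev_date).days == 1
            if member_days and not contiguous:
                close()
            if zone == "basin":
                if member_days and pending_break:
                    member_days.extend(pending_break)
                    pending_break = []
                member_days.append(date)
            elif zone == "break" and member_days and len(pending_break) < bridge_break_days:
                pending_break.append(date)
            else:
                close()
            prev_date = date
        close()
    return pd.DataFrame(
        forays,
        columns=["seal_id", "start_date", "end_date", "duration_days",
                 "max_depth_visited_m", "haulout_hours"],
    )
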