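"""Synthetic biologging data with known ground truth.

Generates everything the downstream pipeline consumes — Argos-style location
fixes, per-dive records, hourly percent-dry summaries, and bathymetry/sea-ice
rasters — from a single seeded configuration, together with the planted truth
(true positions, behavior intervals, and monthly activity budgets) needed to
verify recovery.

The movement model is the same process family the track estimator assumes: an
integrated Ornstein-Uhlenbeck velocity process (continuous-time correlated
random walk) in a planar equal-area frame, observed at irregular times with
Argos-class-dependent isotropic error. Behavior is planted as an explicit,
non-overlapping interval schedule (haul-out / repetitive / mixed / resting)
rather than a hidden Markov chain, so every recovery test has unambiguous
truth.

Study conditions follow the magnitudes a shelf-resident ice seal shows in the
Chukchi-Bering region: fix gaps with median ~0.5 hr, ~7% high-quality Argos
classes, ~6 hr/day hauled out, ~16 hr/day diving of which ~80% is repetitive
diving to consistent depths, dive-record coverage ~30% and percent-dry
coverage ~70% of the deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from . import rasters
from .projection import LambertAzimuthalEqualArea

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

#: published Kalman-class error magnitudes (km) for Argos classes 3..B;
#: Z has no quality guarantee and is emitted as implausible outliers.
DEFAULT_CLASS_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 8.0, "B": 15.0, "Z": 100.0}

DEFAULT_CLASS_PROBS = {"3": 0.02, "2": 0.02, "1": 0.032, "0": 0.08, "A": 0.25, "B": 0.548, "Z": 0.05}


@dataclass
class SimConfig:
    """Configuration for one synthetic deployment cohort."""

    seed: int = 0
    n_seals: int = 1
    start: str | pd.Timestamp = "2016-07-01"
    end: str | pd.Timestamp = "2016-09-30"
    center_lon: float = -170.0
    center_lat: float = 70.0
    # movement
    step_true_min: float = 15.0        # truth-path sampling interval
    ou_beta: float = 1.0               # velocity autocorrelation, 1/hr
    ou_sigma: float = 2.0              # velocity noise scale, km/hr^1.5
    argos_class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    argos_class_sd_km: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SD_KM))
    gap_mean_hr: float = 0.75          # exponential gap between fixes
    long_gap_prob: float = 0.02
    long_gap_range_hr: tuple = (6.0, 24.0)
    # behavior schedule
    behavior_schedule: pd.DataFrame | None = None   # built automatically if None
    haulout_hours_per_day: tuple = (5, 8)           # integer draw [lo, hi)
    rep_target_depth_m: tuple = (40.0, 150.0)
    rep_duration_hr: tuple = (2.0, 4.0)
    mixed_duration_hr: tuple = (0.5, 1.5)
    rest_duration_hr: tuple = (0.5, 1.5)
    class_probs_behavior: tuple = (0.5, 0.3, 0.2)   # repetitive, mixed, resting
    # dive emission
    detection_floor_m: float = 1.0     # tag dive-detection threshold (m); tags vary 1.0-3.5
    depth_jitter_frac: float = 0.06    # repetitive scatter around target
    dd_intercept_min: float = 0.5      # duration = a + b ln(depth) + noise
    dd_slope_min: float = 1.1
    dd_noise_sd_min: float = 0.25
    surface_median_min: float = 0.7    # within-bout surface intervals
    dry_modes: tuple = ((85.0, 100.0), (0.0, 20.0))  # hauled vs wet percent-dry ranges
    # sensor coverage
    dive_coverage: float = 0.30
    dry_coverage: float = 0.72
    # rasters
    grid_cells: int = 80
    cell_km: float = rasters.DEFAULT_CELL_KM

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.end <= self.start:
            raise ValueError("degenerate date range: end must be after start")
        p = sum(self.argos_class_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError(f"argos_class_probs must sum to 1 (got {p})")
        if any(sd < 0 for sd in self.argos_class_sd_km.values()):
            raise ValueError("Argos class error SDs must be >= 0")
        if self.ou_beta <= 0 or self.ou_sigma < 0:
            raise ValueError("require ou_beta > 0 and ou_sigma >= 0")

    @property
    def projection(self) -> LambertAzimuthalEqualArea:
        return LambertAzimuthalEqualArea(self.center_lon, self.center_lat)


@dataclass
class SimTruth:
    """Planted ground truth for one cohort."""

    positions: pd.DataFrame      # seal_id, timestamp, x_km, y_km, lon, lat
    episodes: pd.DataFrame       # seal_id, klass, start, end, target_depth_m
    budget: pd.DataFrame | None  # seal_id, month, haulout_h, repetitive_h, mixed_h, rest_h


@dataclass
class SimBundle:
    """Everything one synthetic cohort produced."""

    config: SimConfig
    fixes: pd.DataFrame
    dives: pd.DataFrame
    drytimes: pd.DataFrame
    coverage: pd.DataFrame
    bathymetry: xr.Dataset
    ice: xr.Dataset
    truth: SimTruth


def _rng(config: SimConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream, extra])


def seal_ids(config: SimConfig) -> list[str]:
    return [f"seal{i + 1:02d}" for i in range(config.n_seals)]


# ---------------------------------------------------------------------------
# behavior schedule
# ---------------------------------------------------------------------------

def build_schedule(config: SimConfig, seal_index: int) -> pd.DataFrame:
    """Interval schedule tiling [start, end) for one seal.

    Each day gets an hour-aligned haul-out window; the remaining time is
    filled with repetitive / mixed / resting intervals (minimum 15 min).
    """
    rng = _rng(config, 3, seal_index)
    sid = seal_ids(config)[seal_index]
    rows = []
    classes = np.array(["repetitive", "mixed", "resting"])
    durs = {
        "repetitive": config.rep_duration_hr,
        "mixed": config.mixed_duration_hr,
        "resting": config.rest_duration_hr,
    }

    def fill(seg_start: pd.Timestamp, seg_end: pd.Timestamp):
        t = seg_start
        while t < seg_end:
            klass = rng.choice(classes, p=config.class_probs_behavior)
            lo, hi = durs[klass]
            dur = pd.Timedelta(hours=float(rng.uniform(lo, hi)))
            end = min(t + dur, seg_end)
            if seg_end - end < pd.Timedelta(minutes=15):
                end = seg_end
            target = float(rng.uniform(*config.rep_target_depth_m)) if klass == "repetitive" else np.nan
            rows.append((sid, klass, t, end, target))
            t = end

    for day in pd.date_range(config.start.normalize(), config.end.normalize(), freq="D"):
        day_start = max(day, config.start)
        day_end = min(day + pd.Timedelta(days=1), config.end)
        if day_end <= day_start:
            continue
        h = int(rng.integers(*config.haulout_hours_per_day))
        h0 = int(rng.integers(1, 24 - h))
        ho_start = max(day + pd.Timedelta(hours=h0), day_start)
        ho_end = min(day + pd.Timedelta(hours=h0 + h), day_end)
        if ho_end > ho_start:
            fill(day_start, ho_start)
            rows.append((sid, "haulout", ho_start, ho_end, np.nan))
            fill(ho_end, day_end)
        else:
            fill(day_start, day_end)

    return pd.DataFrame(rows, columns=["seal_id", "klass", "start", "end", "target_depth_m"])


def true_budget(schedule: pd.DataFrame) -> pd.DataFrame:
    """Planted per-seal-month hours by class, clipped to calendar months."""
    rows = []
    for sid, grp in schedule.groupby("seal_id", sort=True):
        months = pd.period_range(grp["start"].min(), grp["end"].max(), freq="M")
        for m in months:
            m0, m1 = m.start_time, m.end_time + pd.Timedelta(nanoseconds=1)
            hours = {"haulout": 0.0, "repetitive": 0.0, "mixed": 0.0, "resting": 0.0}
            for _, r in grp.iterrows():
                ov = (min(r["end"], m1) - max(r["start"], m0)).total_seconds() / 3600.0
                if ov > 0:
                    hours[r["klass"]] += ov
            if sum(hours.values()) > 0:
                rows.append(
                    (sid, str(m), hours["haulout"], hours["repetitive"], hours["mixed"], hours["resting"])
                )
    return pd.DataFrame(
        rows, columns=["seal_id", "month", "haulout_h", "repetitive_h", "mixed_h", "rest_h"]
    )


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def _iou_increments(beta: float, sigma: float, dt: np.ndarray):
    """Transition scalars and process-noise covariance of the integrated OU.

    For dx = v dt, dv = -beta v dt + sigma dW over steps dt (hours):
    returns (e, phi, qxx, qxv, qvv) with e = exp(-beta dt),
    phi = (1 - e)/beta, and Q the exact discretized covariance.
    """
    e = np.exp(-beta * dt)
    phi = (1.0 - e) / beta
    s2 = sigma**2
    qvv = s2 * (1.0 - e**2) / (2.0 * beta)
    qxv = s2 * (1.0 - e) ** 2 / (2.0 * beta**2)
    qxx = s2 / beta**2 * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e**2) / (2.0 * beta))
    return e, phi, qxx, qxv, qvv


def simulate_track(config: SimConfig, seal_index: int = 0):
    """One seal's true path and Argos fix stream.

    Returns ``(truth_positions, fixes)`` where the truth is sampled on the
    regular ``step_true_min`` grid and the fixes at irregular times with
    class-dependent error. Deterministic given ``config.seed``.
    """
    rng = _rng(config, 0, seal_index)
    sid = seal_ids(config)[seal_index]
    span_hr = (config.end - config.start).total_seconds() / 3600.0

    # irregular observation times (hours since start)
    t_obs = []
    t = 0.0
    while True:
        if rng.uniform() < config.long_gap_prob:
            t += rng.uniform(*config.long_gap_range_hr)
        else:
            t += rng.exponential(config.gap_mean_hr)
        if t >= span_hr:
            break
        t_obs.append(t)
    t_obs = np.asarray(t_obs)

    t_grid = np.arange(0.0, span_hr + 1e-9, config.step_true_min / 60.0)
    t_all = np.union1d(np.round(t_grid, 9), np.round(t_obs, 9))
    dt = np.diff(t_all)

    e, phi, qxx, qxv, qvv = _iou_increments(config.ou_beta, config.ou_sigma, dt)
    # lower Cholesky of each 2x2 Q (qxx may be 0 when sigma == 0)
    l11 = np.sqrt(np.maximum(qxx, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        l21 = np.where(l11 > 0, qxv / np.where(l11 > 0, l11, 1.0), 0.0)
    l22 = np.sqrt(np.maximum(qvv - l21**2, 0.0))

    n = t_all.size
    xy = np.zeros((n, 2))
    v = np.zeros((1, 2))  # start at rest at the origin
    z = rng.standard_normal((n - 1, 4))
    pos = np.zeros(2)
    vel = v[0].copy()
    for k in range(n - 1):
        zx, zvx, zy, zvy = z[k]
        new_x = pos[0] + phi[k] * vel[0] + l11[k] * zx
        new_vx = e[k] * vel[0] + l21[k] * zx + l22[k] * zvx
        new_y = pos[1] + phi[k] * vel[1] + l11[k] * zy
        new_vy = e[k] * vel[1] + l21[k] * zy + l22[k] * zvy
        pos[:] = (new_x, new_y)
        vel[:] = (new_vx, new_vy)
        xy[k + 1] = pos

    times = config.start + pd.to_timedelta(t_all, unit="h")
    proj = config.projection
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    is_grid = np.isin(np.round(t_all, 9), np.round(t_grid, 9))
    truth = pd.DataFrame(
        {
            "seal_id": sid,
            "timestamp": times[is_grid],
            "x_km": xy[is_grid, 0],
            "y_km": xy[is_grid, 1],
            "lon": lon[is_grid],
            "lat": lat[is_grid],
        }
    )

    is_obs = np.isin(np.round(t_all, 9), np.round(t_obs, 9))
    obs_xy = xy[is_obs]
    classes = list(config.argos_class_probs)
    probs = np.array([config.argos_class_probs[c] for c in classes])
    lc = rng.choice(classes, size=obs_xy.shape[0], p=probs)
    sd = np.array([config.argos_class_sd_km[c] for c in lc])
    err = rng.standard_normal(obs_xy.shape) * sd[:, None]
    fx = obs_xy + err
    flon, flat = proj.inverse(fx[:, 0], fx[:, 1])
    fixes = pd.DataFrame(
        {
            "seal_id": sid,
            "timestamp": times[is_obs],
            "lon": flon,
            "lat": flat,
            "lc": lc,
        }
    )
    return truth, fixes


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def simulate_rasters(config: SimConfig, dates=None):
    """Bathymetry/land and daily ice-concentration rasters on the 25-km grid.

    The sea floor runs from a southern mainland strip through a coastal band,
    a shelf (<300 m), a shelf-break ramp, and a basin (>1,000 m) northward; a
    small island sits on the shelf. The ice edge advances south in winter
    (covering the full shelf at >=80% concentration) and retreats poleward
    past the shelf break in late summer.
    """
    grid = rasters.make_grid(config.grid_cells, config.cell_km, config.center_lon, config.center_lat)
    y = grid["y"].values
    n = config.grid_cells
    rng = _rng(config, 2)

    y2d = np.broadcast_to(y[:, None], (n, n)).astype(float)
    coast_y = y.min() + 3 * config.cell_km  # mainland strip: southernmost rows
    land = y2d < coast_y
    d = y2d - coast_y  # km north of the coast
    depth = np.where(
        d < 100.0,
        5.0 + d * 0.55,
        np.where(
            d < 1000.0,
            60.0 + (d - 100.0) * (190.0 / 900.0),
            np.where(
                d < 1200.0,
                300.0 + (d - 1000.0) * (1100.0 / 200.0),
                1400.0 + (d - 1200.0) * 3.0,
            ),
        ),
    )
    relief = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=3.0)
    relief /= max(np.abs(relief).max(), 1e-12)
    depth = depth * (1.0 + 0.08 * relief)
    # an island on the shelf (excluded from mainland distance)
    island = np.zeros_like(land)
    r0 = int(n * 0.35)
    c0 = int(n * 0.65)
    island[r0 : r0 + 2, c0 : c0 + 2] = True
    land = land | island
    depth = np.where(land, np.nan, np.maximum(depth, 2.0))

    bathy = grid.copy()
    bathy["depth"] = (("y", "x"), depth)
    bathy["land"] = (("y", "x"), land.astype(np.int8))

    if dates is None:
        dates = pd.date_range(config.start.normalize(), config.end.normalize(), freq="D")
    else:
        dates = pd.DatetimeIndex(dates)
    fields = np.empty((len(dates), n, n))
    for i, date in enumerate(dates):
        doy = date.dayofyear
        edge_y = -500.0 + 1100.0 * np.cos(2.0 * np.pi * (doy - 258) / 365.25)
        conc = 96.0 / (1.0 + np.exp((edge_y - y2d) / 40.0))
        drng = np.random.default_rng([int(config.seed), 2, int(date.toordinal())])
        noise = ndimage.gaussian_filter(drng.standard_normal((n, n)), sigma=2.0)
        noise = 8.0 * noise / max(np.abs(noise).max(), 1e-12)
        conc = np.clip(conc + noise, 0.0, 100.0)
        fields[i] = np.where(land, np.nan, conc)
    ice = grid.copy()
    ice = ice.assign_coords(time=("time", dates))
    ice["ice_conc"] = (("time", "y", "x"), fields)
    ice["land"] = (("y", "x"), land.astype(np.int8))
    return bathy, ice


# ---------------------------------------------------------------------------
# dive series, percent-dry, coverage
# ---------------------------------------------------------------------------

def _depth_at(bathy: xr.Dataset, truth_pos: pd.DataFrame, when: pd.Timestamp) -> float:
    """Ocean depth under the true position nearest ``when``."""
    idx = truth_pos["timestamp"].searchsorted(when)
    idx = min(max(idx, 0), len(truth_pos) - 1)
    row = truth_pos.iloc[idx]
    iy, ix = rasters.nearest_cell_index(bathy, row["x_km"], row["y_km"])
    val = float(bathy["depth"].values[iy, ix])
    if not np.isfinite(val):
        raise ValueError(f"no bathymetry under track at {when.date()}")
    return val


def _quantize(depths: np.ndarray) -> np.ndarray:
    return np.round(depths * 2.0) / 2.0  # tag depth resolution 0.5 m


def simulate_dive_series(
    config: SimConfig,
    truth: SimTruth,
    bathymetry: xr.Dataset,
    seal_index: int = 0,
):
    """Dive records, hourly percent-dry values, and sensor-coverage windows.

    Emits, per planted interval: repetitive runs of >=5 dives with small
    scatter about the target depth (bounded by local bathymetry) and short
    surface gaps; mixed diving with successive depths forced >15% apart;
    resting intervals with sparse shallow dives separated by >10-min
    surfaces; haul-out intervals with no dives and dry-mode percent-dry
    values. Updates ``truth.budget`` in place.
    """
    rng = _rng(config, 1, seal_index)
    sid = seal_ids(config)[seal_index]
    sched = truth.episodes[truth.episodes["seal_id"] == sid]
    pos = truth.positions[truth.positions["seal_id"] == sid].reset_index(drop=True)
    floor = config.detection_floor_m

    starts, ends, depths = [], [], []

    def emit(t0, t1, depth_m):
        if depth_m < floor:
            return
        starts.append(t0)
        ends.append(t1)
        depths.append(depth_m)

    def surface_short():
        s = float(rng.lognormal(np.log(config.surface_median_min), 0.6))
        return min(max(s, 0.15), 9.5)

    def duration_for(depth_m):
        mu = config.dd_intercept_min + config.dd_slope_min * np.log(max(depth_m, 1.0))
        return float(np.clip(mu + rng.normal(0.0, config.dd_noise_sd_min), 0.5, 14.0))

    for _, itv in sched.iterrows():
        klass = itv["klass"]
        if klass == "haulout":
            continue
        t0, t1 = itv["start"], itv["end"]
        bottom = _depth_at(bathymetry, pos, t0 + (t1 - t0) / 2)
        cap = 0.95 * bottom
        t = t0
        if klass == "repetitive":
            target = min(float(itv["target_depth_m"]), cap)
            while True:
                dep = target * (1.0 + rng.uniform(-config.depth_jitter_frac, config.depth_jitter_frac))
                dep = float(_quantize(np.minimum(dep, cap)))
                dur = duration_for(dep)
                d_end = t + pd.Timedelta(minutes=dur)
                if d_end > t1:
                    break
                emit(t, d_end, dep)
                t = d_end + pd.Timedelta(minutes=surface_short())
        elif klass == "mixed":
            lo, hi = np.log(8.0), np.log(max(min(150.0, cap), 12.0))
            prev: list[float] = []
            while True:
                for _ in range(50):  # force >15% scatter vs both recent depths
                    dep = float(np.exp(rng.uniform(lo, hi)))
                    if all(abs(dep - p) > 0.20 * p for p in prev[-2:]):
                        break
                dep = float(_quantize(np.minimum(dep, cap)))
                dur = duration_for(dep)
                d_end = t + pd.Timedelta(minutes=dur)
                if d_end > t1:
                    break
                emit(t, d_end, dep)
                prev.append(dep)
                t = d_end + pd.Timedelta(minutes=surface_short())
        else:  # resting: long surfaces, occasional shallow dips
            while True:
                t = t + pd.Timedelta(minutes=float(rng.uniform(12.0, 25.0)))
                dep = float(_quantize(np.minimum(rng.uniform(2.0, 8.0), cap)))
                dur = float(rng.uniform(0.5, 1.5))
                d_end = t + pd.Timedelta(minutes=dur)
                if d_end > t1:
                    break
                emit(t, d_end, dep)
                t = d_end

    dives = pd.DataFrame(
        {"seal_id": sid, "start": starts, "end": ends, "max_depth_m": depths}
    ).sort_values("start", ignore_index=True)

    # hourly percent-dry: dry mode inside (hour-aligned) haul-out, wet mode otherwise
    hours = pd.date_range(config.start, config.end, freq="h", inclusive="left")
    ho = sched[sched["klass"] == "haulout"]
    hauled = np.zeros(len(hours), dtype=bool)
    for _, r in ho.iterrows():
        hauled |= (hours >= r["start"]) & (hours + pd.Timedelta(hours=1) <= r["end"])
    (lo_d, hi_d), (lo_w, hi_w) = config.dry_modes
    pdry = np.where(
        hauled,
        rng.uniform(lo_d, hi_d, size=len(hours)),
        rng.uniform(lo_w, hi_w, size=len(hours)),
    )
    keep = rng.uniform(size=len(hours)) < config.dry_coverage
    drytimes = pd.DataFrame(
        {
            "seal_id": sid,
            "date": hours[keep].normalize(),
            "hour": hours[keep].hour,
            "percent_dry": pdry[keep],
        }
    )

    # dive-stream coverage: alternating on/off windows hitting the target fraction
    c = config.dive_coverage
    windows = []
    t = config.start
    on = rng.uniform() < c
    mean_on = 8.0
    mean_off = mean_on * (1.0 - c) / max(c, 1e-9)
    while t < config.end:
        dur = pd.Timedelta(hours=float(rng.exponential(mean_on if on else mean_off)))
        w_end = min(t + dur, config.end)
        if on:
            windows.append((sid, t, w_end))
        t = w_end
        on = not on
    coverage = pd.DataFrame(windows, columns=["seal_id", "start", "end"])

    if not coverage.empty and not dives.empty:
        covered = np.zeros(len(dives), dtype=bool)
        for _, w in coverage.iterrows():
            covered |= (dives["start"].values >= w["start"].to_datetime64()) & (
                dives["end"].values <= w["end"].to_datetime64()
            )
        dives = dives[covered].reset_index(drop=True)
    elif coverage.empty:
        dives = dives.iloc[0:0]

    truth.budget = true_budget(truth.episodes)
    return dives, drytimes, coverage, truth


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimBundle:
    """Simulate a full cohort: tracks, rasters, dives, drytimes, coverage."""
    bathy, ice = simulate_rasters(config)
    all_pos, all_fix, all_sched = [], [], []
    for i in range(config.n_seals):
        truth_i, fixes_i = simulate_track(config, i)
        all_pos.append(truth_i)
        all_fix.append(fixes_i)
        sched = config.behavior_schedule
        if sched is None or sched[sched["seal_id"] == seal_ids(config)[i]].empty:
            sched = build_schedule(config, i)
        else:
            sched = sched[sched["seal_id"] == seal_ids(config)[i]]
        all_sched.append(sched)
    truth = SimTruth(
        positions=pd.concat(all_pos, ignore_index=True),
        episodes=pd.concat(all_sched, ignore_index=True),
        budget=None,
    )
    all_dives, all_dry, all_cov = [], [], []
    for i in range(config.n_seals):
        d, h, cov, truth = simulate_dive_series(config, truth, bathy, i)
        all_dives.append(d)
        all_dry.append(h)
        all_cov.append(cov)
    return SimBundle(
        config=config,
        fixes=pd.concat(all_fix, ignore_index=True),
        dives=pd.concat(all_dives, ignore_index=True),
        drytimes=pd.concat(all_dry, ignore_index=True),
        coverage=pd.concat(all_cov, ignore_index=True),
        bathymetry=bathy,
        ice=ice,
        truth=truth,
    )


def write_fixtures(bundle: SimBundle, outdir) -> dict:
    """Write the cohort as the pipeline's on-disk input formats."""
    import json
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixes": out / "fixes.csv",
        "dives": out / "dives.csv",
        "drytimes": out / "drytimes.csv",
        "coverage": out / "coverage.csv",
        "bathymetry": out / "bathymetry.nc",
        "ice": out / "ice.nc",
        "truth": out / "truth.json",
    }
    bundle.fixes.to_csv(paths["fixes"], index=False)
    bundle.dives.to_csv(paths["dives"], index=False)
    bundle.drytimes.to_csv(paths["drytimes"], index=False)
    bundle.coverage.to_csv(paths["coverage"], index=False)
    rasters.write_netcdf(bundle.bathymetry, paths["bathymetry"])
    rasters.write_netcdf(bundle.ice, paths["ice"])
    truth = {
        "episodes": bundle.truth.episodes.assign(
            start=bundle.truth.episodes["start"].astype(str),
            end=bundle.truth.episodes["end"].astype(str),
        ).to_dict(orient="records"),
        "budget": (
            bundle.truth.budget.to_dict(orient="records") if bundle.truth.budget is not None else []
        ),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, allow_nan=True))
    return {k: str(v) for k, v in paths.items()}
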