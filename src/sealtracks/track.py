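"""Argos fix filtering and continuous-time correlated random walk (CTCRW)
track estimation.

The estimator is the standard movement-ecology state-space model: per axis,
the state is (position, velocity) with Ornstein-Uhlenbeck velocity
(autocorrelation ``beta`` per hour, noise scale ``sigma`` km/hr^1.5) and the
position integrates the velocity. Observations are projected fix coordinates
with known Argos-class error SDs (optionally rescaled by a fitted
multiplier). Parameters are estimated by maximizing the exact Kalman-filter
likelihood; positions on a regular grid come from the Rauch-Tung-Striebel
smoother, and estimates whose standard error exceeds a cutoff (default 25 km)
are dropped before any habitat or behavior analysis.

Processing order: prefilter -> fit -> predict -> SE-drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .projection import haversine_km
from .simulate import DEFAULT_CLASS_SD_KM, _iou_increments

CLASS_QUALITY_ORDER = {"3": 0, "2": 1, "1": 2, "0": 3, "A": 4, "B": 5, "Z": 6}


@dataclass
class CtcrwParams:
    beta: float = 1.0                 # velocity autocorrelation, 1/hr
    sigma: float = 2.0                # velocity noise scale, km/hr^1.5
    error_scale: float = 1.0          # multiplier on the class error SDs
    class_error_sd: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SD_KM))
    loglik: float = np.nan

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.sigma < 0 or any(v < 0 for v in self.class_error_sd.values()):
            raise ValueError("sigma and class error SDs must be >= 0")


# ---------------------------------------------------------------------------
# plausibility prefilter
# ---------------------------------------------------------------------------

def prefilter_fixes(
    fixes: pd.DataFrame,
    land_mask=None,
    max_speed: float = 10.0,
    spike_angle: float = 15.0,
    spike_speed: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove implausible Argos fixes; log every rejection with a reason.

    Steps, per seal: drop class Z; de-duplicate timestamps keeping the
    higher-quality class (ties keep the first); drop fixes on land (if a
    land raster is given); iteratively drop fixes implying > ``max_speed``
    km/hr to *both* neighbors; drop out-and-back spikes (turning angle below
    ``spike_angle`` degrees at speeds above ``spike_speed``).

    Returns ``(retained, rejected)``; ``rejected`` carries a ``reason``
    column. Idempotent on already-filtered data.
    """
    from . import rasters as _rasters

    fixes = fixes.reset_index(drop=True)
    rejected = []

    def reject(df: pd.DataFrame, reason: str):
        if not df.empty:
            rejected.append(df.assign(reason=reason))

    kept_parts = []
    for _, grp in fixes.groupby("seal_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        is_z = grp["lc"].astype(str) == "Z"
        reject(grp[is_z], "class_z")
        grp = grp[~is_z]

        # duplicate timestamps: keep best class, ties keep first
        q = grp["lc"].astype(str).map(CLASS_QUALITY_ORDER)
        order = np.lexsort((np.arange(len(grp)), q.values))
        best = grp.iloc[order].drop_duplicates("timestamp", keep="first")
        dup = grp.loc[~grp.index.isin(best.index)]
        reject(dup, "duplicate_time")
        grp = grp.loc[grp.index.isin(best.index)].sort_values("timestamp", kind="stable")

        if land_mask is not None:
            proj = _rasters.grid_projection(land_mask)
            x, y = proj.forward(grp["lon"].values, grp["lat"].values)
            on_land = np.zeros(len(grp), dtype=bool)
            land = land_mask["land"].values
            for i, (xi, yi) in enumerate(zip(x, y)):
                if _rasters.point_in_grid(land_mask, xi, yi):
                    iy, ix = _rasters.nearest_cell_index(land_mask, xi, yi)
                    on_land[i] = bool(land[iy, ix])
            reject(grp[on_land], "on_land")
            grp = grp[~on_land]

        if len(grp) < 2:
            warnings.warn(f"seal {grp['seal_id'].iloc[0] if len(grp) else '?'}: "
                          "<2 fixes after filtering; passing through", stacklevel=2)
            kept_parts.append(grp)
            continue

        # iterative speed filter: a fix too fast to BOTH neighbors is implausible
        while len(grp) >= 3:
            lon = grp["lon"].values
            lat = grp["lat"].values
            hrs = grp["timestamp"].values.astype("datetime64[s]").astype(float) / 3600.0
            d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
            dt = np.maximum(np.diff(hrs), 1e-6)
            sp = d / dt  # speed on each segment
            bad = (sp[:-1] > max_speed) & (sp[1:] > max_speed)  # interior fixes
            if not bad.any():
                break
            worst = int(np.argmax((sp[:-1] + sp[1:]) * bad)) + 1
            reject(grp.iloc[[worst]], "speed")
            grp = grp.drop(grp.index[worst])

        # spike filter: near out-and-back geometry at implausible speed
        while len(grp) >= 3:
            lon = grp["lon"].values
            lat = grp["lat"].values
            hrs = grp["timestamp"].values.astype("datetime64[s]").astype(float) / 3600.0
            d_in = haversine_km(lon[:-2], lat[:-2], lon[1:-1], lat[1:-1])
            d_out = haversine_km(lon[1:-1], lat[1:-1], lon[2:], lat[2:])
            d_skip = haversine_km(lon[:-2], lat[:-2], lon[2:], lat[2:])
            dt_in = np.maximum(hrs[1:-1] - hrs[:-2], 1e-6)
            dt_out = np.maximum(hrs[2:] - hrs[1:-1], 1e-6)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (d_in**2 + d_out**2 - d_skip**2) / (2 * d_in * d_out)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))  # interior angle
            fast = (d_in / dt_in > spike_speed) & (d_out / dt_out > spike_speed)
            tiny = (d_in > 0.5) & (d_out > 0.5)  # ignore jitter-scale geometry
            bad = fast & tiny & (ang < spike_angle)
            if not bad.any():
                break
            worst = int(np.argmax(bad)) + 1
            reject(grp.iloc[[worst]], "spike")
            grp = grp.drop(grp.index[worst])

        kept_parts.append(grp)

    retained = (
        pd.concat(kept_parts, ignore_index=True) if kept_parts else fixes.iloc[0:0].copy()
    )
    cols = list(fixes.columns) + ["reason"]
    log = (
        pd.concat(rejected, ignore_index=True)[cols]
        if rejected
        else pd.DataFrame(columns=cols)
    )
    return retained, log


# ---------------------------------------------------------------------------
# Kalman machinery (scalar 2-state filter per axis, run on both axes)
# ---------------------------------------------------------------------------

def _filter_axis(times_hr, obs, obs_var, beta, sigma, p0v):
    """Forward Kalman filter for one axis.

    ``obs`` may contain NaN (prediction-only times). Initial state: first
    observation with its own variance and zero velocity with prior variance
    ``p0v``. Returns the log-likelihood and stored moments for smoothing.
    """
    n = len(times_hr)
    e_arr, phi_arr, qxx, qxv, qvv = _iou_increments(beta, sigma, np.diff(times_hr))

    mx = np.empty(n)
    mv = np.empty(n)
    pxx = np.empty(n)
    pxv = np.empty(n)
    pvv = np.empty(n)
    pr_mx = np.empty(n)
    pr_mv = np.empty(n)
    pr_xx = np.empty(n)
    pr_xv = np.empty(n)
    pr_vv = np.empty(n)

    first = int(np.flatnonzero(~np.isnan(obs))[0])
    x, v = obs[first], 0.0
    cxx, cxv, cvv = obs_var[first], 0.0, p0v
    ll = 0.0
    log2pi = np.log(2.0 * np.pi)
    for k in range(n):
        if k > 0:
            e, phi = e_arr[k - 1], phi_arr[k - 1]
            x, v = x + phi * v, e * v
            nxx = cxx + 2.0 * phi * cxv + phi * phi * cvv + qxx[k - 1]
            nxv = e * (cxv + phi * cvv) + qxv[k - 1]
            nvv = e * e * cvv + qvv[k - 1]
            cxx, cxv, cvv = nxx, nxv, nvv
        pr_mx[k], pr_mv[k] = x, v
        pr_xx[k], pr_xv[k], pr_vv[k] = cxx, cxv, cvv
        yk = obs[k]
        if not np.isnan(yk) and k != first:
            s = cxx + obs_var[k]
            innov = yk - x
            ll -= 0.5 * (log2pi + np.log(s) + innov * innov / s)
            kx = cxx / s
            kv = cxv / s
            x += kx * innov
            v += kv * innov
            cvv = cvv - cxv * kv
            cxv = cxv - cxx * kv
            cxx = cxx - cxx * kx
        mx[k], mv[k] = x, v
        pxx[k], pxv[k], pvv[k] = cxx, cxv, cvv
    return ll, (mx, mv, pxx, pxv, pvv), (pr_mx, pr_mv, pr_xx, pr_xv, pr_vv), (e_arr, phi_arr)


def _smooth_axis(filt, pred, trans):
    """RTS smoother over the stored filter pass; returns means and covs.

    Runs in closed-form 2x2 scalar arithmetic (gain G = P_f F' P_pred^-1).
    """
    mx, mv, pxx, pxv, pvv = (a.copy() for a in filt)
    pr_mx, pr_mv, pr_xx, pr_xv, pr_vv = pred
    e_arr, phi_arr = trans
    n = len(mx)
    for k in range(n - 2, -1, -1):
        phi, e = phi_arr[k], e_arr[k]
        a, b, c = pxx[k], pxv[k], pvv[k]
        A, B, C = pr_xx[k + 1], pr_xv[k + 1], pr_vv[k + 1]
        det = A * C - B * B
        if det <= 1e-18:
            continue  # degenerate prediction: smoothed = filtered
        # Pf F' rows
        u1, u2 = a + b * phi, b * e
        w1, w2 = b + c * phi, c * e
        g11 = (u1 * C - u2 * B) / det
        g12 = (-u1 * B + u2 * A) / det
        g21 = (w1 * C - w2 * B) / det
        g22 = (-w1 * B + w2 * A) / det
        dx = mx[k + 1] - pr_mx[k + 1]
        dv = mv[k + 1] - pr_mv[k + 1]
        mx[k] = mx[k] + g11 * dx + g12 * dv
        mv[k] = mv[k] + g21 * dx + g22 * dv
        d1 = pxx[k + 1] - A
        d2 = pxv[k + 1] - B
        d3 = pvv[k + 1] - C
        t11 = g11 * d1 + g12 * d2
        t12 = g11 * d2 + g12 * d3
        t21 = g21 * d1 + g22 * d2
        t22 = g21 * d2 + g22 * d3
        pxx[k] = a + t11 * g11 + t12 * g12
        pxv[k] = b + t11 * g21 + t12 * g22
        pvv[k] = c + t21 * g21 + t22 * g22
    return mx, mv, pxx, pxv, pvv


def _obs_variances(lc: pd.Series, params: CtcrwParams) -> np.ndarray:
    sd = lc.astype(str).map(params.class_error_sd).astype(float).values * params.error_scale
    return np.maximum(sd, 1e-4) ** 2


def _prepare(fixes: pd.DataFrame, proj):
    fixes = fixes.sort_values("timestamp", kind="stable")
    x, y = proj.forward(fixes["lon"].values, fixes["lat"].values)
    t0 = fixes["timestamp"].iloc[0]
    hrs = (fixes["timestamp"] - t0).dt.total_seconds().values / 3600.0
    return fixes, t0, hrs, x, y


def ctcrw_loglik(fixes: pd.DataFrame, params: CtcrwParams, proj) -> float:
    """Exact Kalman log-likelihood of the fixes under ``params``."""
    fixes, _, hrs, x, y = _prepare(fixes, proj)
    r = _obs_variances(fixes["lc"], params)
    p0v = max(params.sigma**2 / (2.0 * params.beta), 1.0)
    ll_x = _filter_axis(hrs, x, r, params.beta, params.sigma, p0v)[0]
    ll_y = _filter_axis(hrs, y, r, params.beta, params.sigma, p0v)[0]
    return ll_x + ll_y


def fit_ctcrw(
    fixes: pd.DataFrame,
    init: CtcrwParams | None = None,
    proj=None,
    fit_error_scale: bool = False,
) -> CtcrwParams:
    """Maximum-likelihood CTCRW parameters for one seal's fixes.

    Optimizes (log beta, log sigma[, log error_scale]) by Nelder-Mead on the
    Kalman likelihood. Raises on non-convergence, attaching the best-so-far
    parameters to the exception.
    """
    if proj is None:
        raise ValueError("an equal-area projection must be supplied")
    if len(fixes) < 10:
        raise ValueError("need >= 10 retained fixes to fit the CTCRW")
    init = init or CtcrwParams()
    fixes, _, hrs, x, y = _prepare(fixes, proj)
    r0 = _obs_variances(fixes["lc"], init)

    def negll(theta):
        beta = np.exp(theta[0])
        sigma = np.exp(theta[1])
        if not (1e-4 < beta < 1e3) or not (sigma < 1e3):
            return 1e12
        r = r0 * (np.exp(2.0 * theta[2]) if fit_error_scale else 1.0)
        p0v = max(sigma**2 / (2.0 * beta), 1.0)
        ll = (
            _filter_axis(hrs, x, r, beta, sigma, p0v)[0]
            + _filter_axis(hrs, y, r, beta, sigma, p0v)[0]
        )
        return -ll if np.isfinite(ll) else 1e12

    x0 = [np.log(init.beta), np.log(max(init.sigma, 1e-3))]
    if fit_error_scale:
        x0.append(np.log(init.error_scale))
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600})
    out = CtcrwParams(
        beta=float(np.exp(res.x[0])),
        sigma=float(np.exp(res.x[1])),
        error_scale=float(np.exp(res.x[2])) if fit_error_scale else init.error_scale,
        class_error_sd=dict(init.class_error_sd),
        loglik=float(-res.fun),
    )
    if not res.success:
        err = RuntimeError(f"CTCRW fit did not converge: {res.message}")
        err.best_params = out
        raise err
    return out


def predict_track(
    params: CtcrwParams,
    fixes: pd.DataFrame,
    proj,
    grid_step_hr: float = 6.0,
    se_max_km: float = 25.0,
):
    """Smoothed positions on a regular grid, dropping high-SE estimates.

    The grid is anchored to whole multiples of ``grid_step_hr`` from
    midnight UTC. Returns ``(estimates, n_dropped)`` where ``se_km`` is the
    RMS of the per-axis posterior position SDs.
    """
    fixes, t0, hrs, x, y = _prepare(fixes, proj)
    t_end = hrs[-1]
    anchor = t0.ceil(f"{int(grid_step_hr * 60)}min")
    g0 = (anchor - t0).total_seconds() / 3600.0
    grid_hrs = np.arange(g0, t_end + 1e-9, grid_step_hr)
    if grid_hrs.size == 0:
        return fixes.iloc[0:0].assign(x_km=[], y_km=[], se_km=[]), 0

    t_all = np.union1d(np.round(hrs, 9), np.round(grid_hrs, 9))
    obs_x = np.full(t_all.size, np.nan)
    obs_y = np.full(t_all.size, np.nan)
    rvar = np.full(t_all.size, np.nan)
    idx = np.searchsorted(t_all, np.round(hrs, 9))
    obs_x[idx] = x
    obs_y[idx] = y
    rvar[idx] = _obs_variances(fixes["lc"], params)

    p0v = max(params.sigma**2 / (2.0 * params.beta), 1.0)
    sx = _smooth_axis(*_filter_axis(t_all, obs_x, rvar, params.beta, params.sigma, p0v)[1:])
    sy = _smooth_axis(*_filter_axis(t_all, obs_y, rvar, params.beta, params.sigma, p0v)[1:])

    gi = np.searchsorted(t_all, np.round(grid_hrs, 9))
    ex, ey = sx[0][gi], sy[0][gi]
    var = 0.5 * (np.maximum(sx[2][gi], 0.0) + np.maximum(sy[2][gi], 0.0))
    se = np.sqrt(var)
    lon, lat = proj.inverse(ex, ey)
    est = pd.DataFrame(
        {
            "seal_id": fixes["seal_id"].iloc[0],
            "timestamp": t0 + pd.to_timedelta(grid_hrs, unit="h"),
            "lon": lon,
            "lat": lat,
            "x_km": ex,
            "y_km": ey,
            "se_km": se,
        }
    )
    ok = est["se_km"] <= se_max_km
    return est[ok].reset_index(drop=True), int((~ok).sum())


def smooth_at_times(params: CtcrwParams, fixes: pd.DataFrame, proj, times_hr: np.ndarray):
    """Smoothed per-axis means and position variances at arbitrary offsets
    (hours from the first fix). Used for coverage checks against truth."""
    fixes, t0, hrs, x, y = _prepare(fixes, proj)
    t_all = np.union1d(np.round(hrs, 9), np.round(times_hr, 9))
    obs_x = np.full(t_all.size, np.nan)
    obs_y = np.full(t_all.size, np.nan)
    rvar = np.full(t_all.size, np.nan)
    idx = np.searchsorted(t_all, np.round(hrs, 9))
    obs_x[idx] = x
    obs_y[idx] = y
    rvar[idx] = _obs_variances(fixes["lc"], params)
    p0v = max(params.sigma**2 / (2.0 * params.beta), 1.0)
    sx = _smooth_axis(*_filter_axis(t_all, obs_x, rvar, params.beta, params.sigma, p0v)[1:])
    sy = _smooth_axis(*_filter_axis(t_all, obs_y, rvar, params.beta, params.sigma, p0v)[1:])
    gi = np.searchsorted(t_all, np.round(times_hr, 9))
    return sx[0][gi], sy[0][gi], np.maximum(sx[2][gi], 0.0), np.maximum(sy[2][gi], 0.0)


# ---------------------------------------------------------------------------
# daily summaries
# ---------------------------------------------------------------------------

def daily_summaries(track: pd.DataFrame) -> pd.DataFrame:
    """Per-day midday position, step distance, cumulative distance, rate.

    The daily position is the estimate nearest 12:00 UTC. The day's distance
    sums great-circle steps between consecutive estimates whose *second*
    endpoint falls in the day; days with no estimates are flagged missing
    (no interpolation) and do not advance the cumulative distance.
    """
    if len(track) < 2:
        raise ValueError("need >= 2 track estimates")
    out_rows = []
    for sid, grp in track.groupby("seal_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        step = np.zeros(len(grp))
        step[1:] = haversine_km(
            grp["lon"].values[:-1], grp["lat"].values[:-1],
            grp["lon"].values[1:], grp["lat"].values[1:],
        )
        grp = grp.assign(_step=step, _date=grp["timestamp"].dt.normalize())
        days = pd.date_range(grp["_date"].iloc[0], grp["_date"].iloc[-1], freq="D")
        cum = 0.0
        for day in days:
            sub = grp[grp["_date"] == day]
            if sub.empty:
                out_rows.append((sid, day, np.nan, np.nan, np.nan, np.nan, cum, True))
                continue
            midday = day + pd.Timedelta(hours=12)
            i = (sub["timestamp"] - midday).abs().idxmin()
            dist = float(sub["_step"].sum())
            cum += dist
            out_rows.append(
                (sid, day, grp.loc[i, "lon"], grp.loc[i, "lat"],
                 grp.loc[i, "timestamp"], dist, cum, False)
            )
    return pd.DataFrame(
        out_rows,
        columns=["seal_id", "date", "lon", "lat", "midday_timestamp",
                 "distance_km", "cumulative_km", "missing"],
    )
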