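"""Prefilter rules, Kalman smoother correctness (vs a dense joint-Gaussian
solve), prediction SE behavior, and daily summaries."""

import numpy as np
import pandas as pd
import pytest

from sealtracks import (
    CtcrwParams,
    SimConfig,
    ctcrw_loglik,
    daily_summaries,
    fit_ctcrw,
    predict_track,
    prefilter_fixes,
    simulate_track,
)
from sealtracks.projection import LambertAzimuthalEqualArea
from sealtracks.simulate import _iou_increments
from sealtracks.track import _filter_axis, _smooth_axis

PROJ = LambertAzimuthalEqualArea(-170.0, 70.0)


def fixes_from_xy(xy, hours, lc="3", seal="s1"):
    lon, lat = PROJ.inverse(np.asarray(xy, float)[:, 0], np.asarray(xy, float)[:, 1])
    return pd.DataFrame(
        {
            "seal_id": seal,
            "timestamp": pd.Timestamp("2016-07-01") + pd.to_timedelta(hours, unit="h"),
            "lon": lon,
            "lat": lat,
            "lc": lc,
        }
    )


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------

class TestPrefilter:
    def test_speed_violator_removed(self):
        # A at origin, B 100 km away after 1 hr, back at A' after another hour
        fx = fixes_from_xy([(0, 0), (100, 0), (0, 0)], [0, 1, 2])
        kept, log = prefilter_fixes(fx, max_speed=10.0)
        assert len(kept) == 2
        assert log["reason"].tolist() == ["speed"]

    def test_plausible_straight_track_untouched(self):
        xy = [(i * 2.0, 0.0) for i in range(10)]  # 2 km/hr
        fx = fixes_from_xy(xy, np.arange(10.0))
        kept, log = prefilter_fixes(fx, max_speed=10.0)
        assert len(kept) == 10 and log.empty

    def test_spike_geometry_removed(self):
        # out-and-back 8 km at ~7 km/hr with near-zero turning angle
        fx = fixes_from_xy([(0, 0), (2, 0), (10, 0.1), (4, 0), (6, 0)], [0, 1, 2.1, 3.2, 4.2])
        kept, log = prefilter_fixes(fx, max_speed=50.0, spike_angle=15.0, spike_speed=5.0)
        assert "spike" in log["reason"].tolist()
        assert len(kept) == 4

    def test_on_land_fix_removed(self, small_grid):
        lon_land = small_grid["lon"].values[0, 5]
        lat_land = small_grid["lat"].values[0, 5]
        lon_sea = small_grid["lon"].values[6, 5]
        lat_sea = small_grid["lat"].values[6, 5]
        fx = pd.DataFrame(
            {
                "seal_id": "s1",
                "timestamp": pd.to_datetime(["2016-07-01 00:00", "2016-07-01 06:00", "2016-07-01 12:00"]),
                "lon": [lon_sea, lon_land, lon_sea],
                "lat": [lat_sea, lat_land, lat_sea],
                "lc": "3",
            }
        )
        kept, log = prefilter_fixes(fx, land_mask=small_grid)
        assert log["reason"].tolist() == ["on_land"]
        assert len(kept) == 2

    def test_class_z_dropped_and_duplicates_keep_best(self):
        t = pd.Timestamp("2016-07-01")
        fx = pd.DataFrame(
            {
                "seal_id": "s1",
                "timestamp": [t, t, t + pd.Timedelta(hours=1), t + pd.Timedelta(hours=2)],
                "lon": [-170.0, -170.01, -170.0, -170.0],
                "lat": [70.0, 70.0, 70.01, 70.02],
                "lc": ["B", "2", "Z", "3"],
            }
        )
        kept, log = prefilter_fixes(fx)
        assert set(log["reason"]) == {"class_z", "duplicate_time"}
        assert kept["lc"].tolist() == ["2", "3"]

    def test_single_fix_passes_with_warning(self):
        fx = fixes_from_xy([(0, 0)], [0])
        with pytest.warns(UserWarning, match="<2 fixes"):
            kept, _ = prefilter_fixes(fx)
        assert len(kept) == 1

    def test_idempotent_on_filtered_data(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 1.0, (50, 2)), axis=0)
        fx = fixes_from_xy(xy, np.arange(50) * 0.5)
        kept1, _ = prefilter_fixes(fx)
        kept2, log2 = prefilter_fixes(kept1)
        assert log2.empty
        pd.testing.assert_frame_equal(kept1.reset_index(drop=True), kept2)


# ---------------------------------------------------------------------------
# smoother oracle: dense joint-Gaussian solve on a 3-fix toy problem
# ---------------------------------------------------------------------------

def dense_smoother_oracle(times, y, r, beta, sigma, p0v):
    """Posterior state means by explicit Gaussian conditioning.

    Prior: s1 ~ N((y1, 0), diag(r1, p0v)); s_{k+1} = F_k s_k + w_k.
    Conditions on y_2..y_n (y_1 enters through the prior, mirroring the
    filter's initialization).
    """
    n = len(times)
    dts = np.diff(times)
    e, phi, qxx, qxv, qvv = _iou_increments(beta, sigma, np.asarray(dts, float))
    Fs = [np.array([[1.0, phi[k]], [0.0, e[k]]]) for k in range(n - 1)]
    Qs = [np.array([[qxx[k], qxv[k]], [qxv[k], qvv[k]]]) for k in range(n - 1)]
    # joint of stacked states via propagation
    mu = np.zeros(2 * n)
    mu[0] = y[0]
    cov = np.zeros((2 * n, 2 * n))
    cov[:2, :2] = np.diag([r[0], p0v])
    for k in range(n - 1):
        F = Fs[k]
        mu[2 * (k + 1) : 2 * (k + 2)] = F @ mu[2 * k : 2 * (k + 1)]
        # propagate covariances against all earlier blocks
        for j in range(k + 1):
            cov_jk = cov[2 * j : 2 * (j + 1), 2 * k : 2 * (k + 1)]
            cov[2 * j : 2 * (j + 1), 2 * (k + 1) : 2 * (k + 2)] = cov_jk @ F.T
            cov[2 * (k + 1) : 2 * (k + 2), 2 * j : 2 * (j + 1)] = (cov_jk @ F.T).T
        Pk = cov[2 * k : 2 * (k + 1), 2 * k : 2 * (k + 1)]
        cov[2 * (k + 1) : 2 * (k + 2), 2 * (k + 1) : 2 * (k + 2)] = F @ Pk @ F.T + Qs[k]
    H = np.zeros((n - 1, 2 * n))
    for k in range(1, n):
        H[k - 1, 2 * k] = 1.0
    R = np.diag(np.asarray(r[1:], float))
    S = H @ cov @ H.T + R
    gain = cov @ H.T @ np.linalg.inv(S)
    post = mu + gain @ (np.asarray(y[1:], float) - H @ mu)
    return post.reshape(n, 2)


def test_smoother_matches_dense_gls_solve():
    times = np.array([0.0, 1.0, 3.0])
    y = np.array([0.0, 5.0, 2.0])
    r = np.array([1.0, 0.5, 2.0])
    beta, sigma, p0v = 0.8, 1.5, 4.0
    expect = dense_smoother_oracle(times, y, r, beta, sigma, p0v)
    _, filt, pred, trans = _filter_axis(times, y, r, beta, sigma, p0v)
    mx, mv, *_ = _smooth_axis(filt, pred, trans)
    assert np.allclose(mx, expect[:, 0], atol=1e-6)
    assert np.allclose(mv, expect[:, 1], atol=1e-6)


def test_smoother_matches_oracle_with_prediction_times():
    # same check with an unobserved (prediction-only) interior time
    times = np.array([0.0, 0.7, 1.0, 2.2, 3.0])
    y_full = np.array([1.0, np.nan, -2.0, np.nan, 4.0])
    r_full = np.array([0.6, np.nan, 0.8, np.nan, 1.2])
    beta, sigma, p0v = 1.2, 2.0, 3.0
    obs = ~np.isnan(y_full)
    expect_obs = dense_smoother_oracle(times[obs], y_full[obs], r_full[obs], beta, sigma, p0v)
    _, filt, pred, trans = _filter_axis(times, y_full, r_full, beta, sigma, p0v)
    mx, mv, *_ = _smooth_axis(filt, pred, trans)
    assert np.allclose(mx[obs], expect_obs[:, 0], atol=1e-6)
    assert np.allclose(mv[obs], expect_obs[:, 1], atol=1e-6)


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

QUALITY = {"3": 0.4, "2": 0.4, "1": 0.2, "0": 0.0, "A": 0.0, "B": 0.0, "Z": 0.0}


@pytest.fixture(scope="module")
def sim_track():
    cfg = SimConfig(seed=4, start="2016-07-01", end="2016-07-22",
                    argos_class_probs=QUALITY)
    truth, fixes = simulate_track(cfg, 0)
    return cfg, truth, fixes


def test_fit_requires_min_fixes():
    fx = fixes_from_xy([(0, 0)] * 5, np.arange(5.0))
    with pytest.raises(ValueError, match=">= 10"):
        fit_ctcrw(fx, proj=PROJ)


def test_fitted_likelihood_beats_init(sim_track):
    cfg, _, fixes = sim_track
    init = CtcrwParams(beta=0.3, sigma=0.5)
    fitted = fit_ctcrw(fixes, init=init, proj=cfg.projection)
    assert fitted.loglik >= ctcrw_loglik(fixes, init, cfg.projection)


def test_prediction_passes_through_noisefree_fixes():
    # dense, noise-free observations: the smoother must interpolate them
    rng = np.random.default_rng(1)
    hours = np.arange(0, 48.0, 0.5)
    xy = np.cumsum(rng.normal(0, 0.5, (len(hours), 2)), axis=0)
    fx = fixes_from_xy(xy, hours)
    params = CtcrwParams(beta=1.0, sigma=2.0,
                         class_error_sd={**{c: 0.0 for c in "3210ABZ"}})
    est, _ = predict_track(params, fx, PROJ, grid_step_hr=6.0, se_max_km=np.inf)
    # grid times at whole 6-hr offsets coincide with observation times
    merged = est.merge(fx, on="timestamp", suffixes=("_e", "_o"))
    assert len(merged) > 0
    ex, ey = PROJ.forward(merged["lon_e"].values, merged["lat_e"].values)
    ox, oy = PROJ.forward(merged["lon_o"].values, merged["lat_o"].values)
    assert np.allclose(ex, ox, atol=1e-3) and np.allclose(ey, oy, atol=1e-3)
    assert (merged["se_km"] < 0.02).all()


def test_se_grows_into_a_data_gap(sim_track):
    cfg, _, fixes = sim_track
    # carve a 48-hr hole in the middle of the record
    t0 = fixes["timestamp"].min() + pd.Timedelta(days=8)
    gap = (fixes["timestamp"] > t0) & (fixes["timestamp"] < t0 + pd.Timedelta(hours=48))
    holed = fixes[~gap]
    params = fit_ctcrw(holed, proj=cfg.projection)
    est, _ = predict_track(params, holed, cfg.projection, se_max_km=np.inf)
    inside = est[(est["timestamp"] > t0) & (est["timestamp"] < t0 + pd.Timedelta(hours=48))]
    assert len(inside) >= 6
    se = inside["se_km"].values
    peak = int(np.argmax(se))
    # SE is unimodal across the gap: rises to a peak, then falls, and the
    # peak exceeds the SE at both gap edges
    assert 0 < peak < len(se) - 1
    assert (np.diff(se[: peak + 1]) >= -1e-9).all()
    assert (np.diff(se[peak:]) <= 1e-9).all()
    assert se[peak] > se[0] and se[peak] > se[-1]


def test_se_max_infinite_drops_nothing(sim_track):
    cfg, _, fixes = sim_track
    params = fit_ctcrw(fixes, proj=cfg.projection)
    _, dropped = predict_track(params, fixes, cfg.projection, se_max_km=np.inf)
    assert dropped == 0


def test_grid_spacing_exactly_six_hours(sim_track):
    cfg, _, fixes = sim_track
    params = fit_ctcrw(fixes, proj=cfg.projection)
    est, _ = predict_track(params, fixes, cfg.projection, se_max_km=np.inf)
    steps = est["timestamp"].diff().dropna().dt.total_seconds() / 3600.0
    assert (steps == 6.0).all()
    assert np.isfinite(est["se_km"]).all()


def test_grid_outside_span_empty():
    # 2.5-hr record starting at 00:30: the first 6-hr grid point (06:00)
    # falls past the last fix, so there is nothing to estimate
    fx = fixes_from_xy([(0, 0), (1, 0)], [0.5, 2.5])
    params = CtcrwParams()
    est, dropped = predict_track(params, fx, PROJ, grid_step_hr=6.0)
    assert est.empty and dropped == 0


# ---------------------------------------------------------------------------
# daily summaries
# ---------------------------------------------------------------------------

def grid_track(xy_steps, seal="s1"):
    hours = np.arange(len(xy_steps)) * 6.0
    return fixes_from_xy(xy_steps, hours, seal=seal).rename(columns={"lc": "_"}).drop(columns="_")


def test_stationary_track_zero_distance():
    tr = grid_track([(0.0, 0.0)] * 8)
    ds = daily_summaries(tr)
    assert ds["cumulative_km"].iloc[-1] == pytest.approx(0.0, abs=1e-9)


def test_constant_step_distances():
    # 4 km per 6-hr step for 10 days -> 160 km cumulative, 16 km/day
    n = 41  # 40 steps = 10 days
    tr = grid_track([(4.0 * i, 0.0) for i in range(n)])
    ds = daily_summaries(tr)
    full_days = ds[~ds["missing"]].iloc[:10]
    assert full_days["distance_km"].iloc[1] == pytest.approx(16.0, rel=1e-4)
    assert ds["cumulative_km"].iloc[-1] == pytest.approx(160.0, rel=1e-4)


def test_missing_day_flagged_not_interpolated():
    xy = [(i * 1.0, 0.0) for i in range(12)]
    tr = grid_track(xy)
    # remove all of day 2
    day2 = pd.Timestamp("2016-07-02")
    tr = tr[~((tr["timestamp"] >= day2) & (tr["timestamp"] < day2 + pd.Timedelta(days=1)))]
    ds = daily_summaries(tr)
    missing = ds[ds["date"] == day2]
    assert missing["missing"].iloc[0]
    assert np.isnan(missing["lon"].iloc[0])
    # cumulative distance is monotone despite the hole
    cum = ds["cumulative_km"].values
    assert (np.diff(cum) >= -1e-12).all()
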