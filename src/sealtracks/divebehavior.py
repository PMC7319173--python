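"""Haul-out classification, dive-bout segmentation, bottom-dive calls,
diel profiles, dive histograms, and the depth-duration regression.

Segmentation rule
-----------------
The dive record is first split wherever the surface interval between
successive dives exceeds 10 min (a *resting* boundary). Within a segment a
dive is *consistent* when its maximum depth lies within +/-15% of the depth
of either of the two preceding dives (tolerance taken relative to the
preceding dive's depth). Maximal chains holding >=5 consistent dives form
*repetitive-diving* episodes; a single inconsistent dive is allowable inside
an episode, but two consecutive inconsistent dives end it. Everything else
is *mixed* diving. The precise tie-breaks (how inconsistent dives at chain
edges are handled) are documented in docs/methods.md and encoded in
:func:`segment_behavior`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class DepthDurationFit:
    """duration = a + b * ln(depth) fitted on 10-m depth-bin medians."""

    a: float
    b: float
    s: float       # standard error of the regression, minutes
    n_bins: int
    n_dives: int


# ---------------------------------------------------------------------------
# haul-out hours
# ---------------------------------------------------------------------------

def classify_haulout_hours(drytimes: pd.DataFrame, threshold: float = 80.0):
    """Flag haul-out hours (percent dry >= threshold) and tabulate bouts.

    Bouts are maximal runs of consecutive flagged hours; missing hours break
    bouts (no bridging). Returns ``(flags, bouts)``: flags carries one row
    per observed hour with a boolean ``haulout``; bouts one row per bout
    with whole-hour duration.
    """
    flags = drytimes.copy()
    flags["date"] = pd.to_datetime(flags["date"]).dt.normalize()
    flags["hour_start"] = flags["date"] + pd.to_timedelta(flags["hour"], unit="h")
    flags["haulout"] = flags["percent_dry"] >= threshold
    flags = flags.sort_values(["seal_id", "hour_start"], ignore_index=True)

    bouts = []
    for sid, grp in flags[flags["haulout"]].groupby("seal_id", sort=True):
        hs = grp["hour_start"].reset_index(drop=True)
        if hs.empty:
            continue
        gap = hs.diff() != pd.Timedelta(hours=1)
        bout_id = gap.cumsum()
        for _, b in hs.groupby(bout_id):
            bouts.append((sid, b.iloc[0], b.iloc[-1] + pd.Timedelta(hours=1), len(b)))
    bouts = pd.DataFrame(bouts, columns=["seal_id", "start", "end", "duration_h"])
    return flags, bouts


# ---------------------------------------------------------------------------
# surface intervals
# ---------------------------------------------------------------------------

def derive_surface_intervals(dives: pd.DataFrame, haulout_flags: pd.DataFrame | None = None):
    """One surface interval between each pair of consecutive dives.

    ``overlaps_haulout`` is True when the interval intersects any flagged
    haul-out hour of the same seal.
    """
    rows = []
    for sid, grp in dives.groupby("seal_id", sort=True):
        grp = grp.sort_values("start", kind="stable")
        s = grp["end"].values[:-1]
        e = grp["start"].values[1:]
        for a, b in zip(s, e):
            rows.append((sid, pd.Timestamp(a), pd.Timestamp(b)))
    out = pd.DataFrame(rows, columns=["seal_id", "start", "end"])
    out["duration_min"] = (out["end"] - out["start"]).dt.total_seconds() / 60.0
    out["overlaps_haulout"] = False
    if haulout_flags is not None and not out.empty:
        ho = haulout_flags[haulout_flags["haulout"]]
        for sid, grp in ho.groupby("seal_id", sort=False):
            hs = grp["hour_start"].values
            he = hs + np.timedelta64(1, "h")
            mask = out["seal_id"] == sid
            sub = out[mask]
            ov = np.zeros(len(sub), dtype=bool)
            for a, b in zip(hs, he):
                ov |= (sub["start"].values < b) & (sub["end"].values > a)
            out.loc[mask, "overlaps_haulout"] = ov
    return out


# ---------------------------------------------------------------------------
# behavior segmentation
# ---------------------------------------------------------------------------

def _consistency_flags(depths: np.ndarray, tol: float, min_denom: float) -> np.ndarray:
    """flag[j] (j>=1): dive j within tol of either of dives j-1, j-2."""
    n = len(depths)
    flags = np.zeros(n, dtype=bool)
    for j in range(1, n):
        ok = False
        for p in (j - 1, j - 2):
            if p >= 0:
                denom = max(depths[p], min_denom)
                if abs(depths[j] - depths[p]) <= tol * denom:
                    ok = True
                    break
        flags[j] = ok
    return flags


def _segment_one(depths: np.ndarray, tol: float, rep_min: int, min_denom: float):
    """Episode labels for one resting-bounded segment.

    Returns a list of (start_idx, end_idx_inclusive, klass) partitioning the
    segment into repetitive blocks and mixed remainders. A transition flag
    marks each dive consistent/inconsistent with its two predecessors; an
    inconsistent dive is tolerated inside a chain only when isolated (its
    neighboring transitions are consistent), and chains are cut at every
    non-isolated inconsistency. Chains are then trimmed of leading/trailing
    inconsistent members and called repetitive when >=``rep_min`` consistent
    members remain.
    """
    n = len(depths)
    if n == 0:
        return []
    flags = _consistency_flags(depths, tol, min_denom)
    # cut the edge into dive j when its transition is inconsistent and not isolated
    cut = np.zeros(n, dtype=bool)  # cut[j]: split between j-1 and j
    for j in range(1, n):
        if not flags[j]:
            left_bad = (j - 1 >= 1) and (not flags[j - 1])
            right_bad = (j + 1 < n) and (not flags[j + 1])
            cut[j] = left_bad or right_bad
    # chains = maximal uncut runs
    blocks = []
    s = 0
    for j in range(1, n + 1):
        if j == n or cut[j]:
            blocks.append((s, j - 1))
            s = j
    out = []
    for s, e in blocks:
        # a trailing inconsistent member is not "within" the episode: split it off
        s2, e2 = s, e
        while e2 > s2 and not flags[e2]:
            out.append((e2, e2, "mixed"))
            e2 -= 1
        n_members = e2 - s2 + 1
        n_dev = int(np.sum(~flags[s2 + 1 : e2 + 1]))
        n_consistent = n_members - n_dev
        klass = "repetitive" if n_consistent >= rep_min else "mixed"
        out.append((s2, e2, klass))
    out.sort()
    # merge adjacent mixed singletons into maximal mixed episodes
    merged = []
    for s, e, k in out:
        if merged and k == "mixed" and merged[-1][2] == "mixed" and merged[-1][1] == s - 1:
            merged[-1] = (merged[-1][0], e, "mixed")
        else:
            merged.append((s, e, k))
    return merged


def segment_behavior(
    dives: pd.DataFrame,
    surfaces: pd.DataFrame | None = None,
    rest_surface_min: float = 10.0,
    rep_tol: float = 0.15,
    rep_min_dives: int = 5,
    min_denom_depth: float = 2.0,
) -> pd.DataFrame:
    """Partition the dive record into resting / repetitive / mixed episodes.

    Every dive belongs to exactly one episode; surface intervals longer than
    ``rest_surface_min`` minutes become resting episodes. Returns one row
    per episode: seal_id, klass, start, end, n_dives, median_depth_m,
    dive_index_start/end (positions into the seal's time-ordered dives).
    """
    episodes = []
    for sid, grp in dives.groupby("seal_id", sort=True):
        grp = grp.sort_values("start", kind="stable").reset_index(drop=True)
        if grp.empty:
            continue
        gaps = (
            (grp["start"].values[1:] - grp["end"].values[:-1])
            / np.timedelta64(1, "m")
        )
        seg_break = np.flatnonzero(gaps > rest_surface_min)
        seg_starts = np.r_[0, seg_break + 1]
        seg_ends = np.r_[seg_break, len(grp) - 1]
        for gs, ge in zip(seg_starts, seg_ends):
            depths = grp["max_depth_m"].values[gs : ge + 1].astype(float)
            for s, e, klass in _segment_one(depths, rep_tol, rep_min_dives, min_denom_depth):
                sub = grp.iloc[gs + s : gs + e + 1]
                episodes.append(
                    (
                        sid,
                        klass,
                        sub["start"].iloc[0],
                        sub["end"].iloc[-1],
                        len(sub),
                        float(np.median(sub["max_depth_m"].values)),
                        gs + s,
                        gs + e,
                    )
                )
        # resting episodes from the long surfaces
        for j in seg_break:
            episodes.append(
                (
                    sid,
                    "resting",
                    grp["end"].iloc[j],
                    grp["start"].iloc[j + 1],
                    0,
                    np.nan,
                    -1,
                    -1,
                )
            )
    out = pd.DataFrame(
        episodes,
        columns=["seal_id", "klass", "start", "end", "n_dives",
                 "median_depth_m", "dive_index_start", "dive_index_end"],
    )
    return out.sort_values(["seal_id", "start"], ignore_index=True)


def flag_resting_overlaps(episodes: pd.DataFrame, haulout_flags: pd.DataFrame) -> pd.DataFrame:
    """Mark resting episodes that intersect a flagged haul-out hour.

    Overlapping resting time has already been tallied as haul-out in the
    budget and must be discarded from the resting pool.
    """
    out = episodes.copy()
    out["overlaps_haulout"] = False
    ho = haulout_flags[haulout_flags["haulout"]]
    rest = out["klass"] == "resting"
    for sid, grp in ho.groupby("seal_id", sort=False):
        hs = grp["hour_start"].values
        he = hs + np.timedelta64(1, "h")
        mask = rest & (out["seal_id"] == sid)
        sub = out[mask]
        ov = np.zeros(len(sub), dtype=bool)
        for a, b in zip(hs, he):
            ov |= (sub["start"].values < b) & (sub["end"].values > a)
        out.loc[mask, "overlaps_haulout"] = ov
    return out


def label_dives(dives: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Attach each dive's episode class (repetitive/mixed) to the dive table."""
    out = []
    for sid, grp in dives.groupby("seal_id", sort=True):
        grp = grp.sort_values("start", kind="stable").reset_index(drop=True)
        lab = np.array(["mixed"] * len(grp), dtype=object)
        med = np.full(len(grp), np.nan)
        eps = episodes[(episodes["seal_id"] == sid) & (episodes["klass"] != "resting")]
        for _, r in eps.iterrows():
            lab[int(r["dive_index_start"]) : int(r["dive_index_end"]) + 1] = r["klass"]
            med[int(r["dive_index_start"]) : int(r["dive_index_end"]) + 1] = r["median_depth_m"]
        out.append(grp.assign(klass=lab, episode_median_depth_m=med))
    return pd.concat(out, ignore_index=True) if out else dives.assign(klass=[], episode_median_depth_m=[])


# ---------------------------------------------------------------------------
# bottom dives
# ---------------------------------------------------------------------------

def classify_bottom_dive(max_depth_m, ocean_depth_m, bottom_frac: float = 0.75,
                         min_ocean_depth_m: float = 10.0):
    """'bottom' when the dive reaches >= 75% of the mapped ocean depth.

    Shallow water (< 10 m mapped depth) is 'indeterminate'; dives exceeding
    the mapped depth (location/bathymetry mismatch) still count as bottom.
    Vectorized over inputs.
    """
    depth = np.asarray(max_depth_m, dtype=float)
    ocean = np.asarray(ocean_depth_m, dtype=float)
    out = np.where(
        (ocean < min_ocean_depth_m) | ~np.isfinite(ocean),
        "indeterminate",
        np.where(depth / np.maximum(ocean, 1e-9) >= bottom_frac, "bottom", "pelagic"),
    )
    return out if out.ndim else out.item()


# ---------------------------------------------------------------------------
# diel profiles and histograms
# ---------------------------------------------------------------------------

def diel_monthly_profiles(
    labeled_dives: pd.DataFrame,
    episodes: pd.DataFrame,
    haulout_flags: pd.DataFrame | None = None,
    local_offset_hr: float = -10.0,
    depth_split_m: float = 25.0,
):
    """Hour-of-day x month event-proportion matrices in local time.

    Four dive-class matrices (repetitive deeper/shallower than the depth
    split by episode median depth, mixed, resting) are each normalized so a
    month's 24 hourly proportions sum to 1. When haul-out flags are given, a
    fifth matrix holds the across-seal mean (and SE) of each seal's hourly
    haul-out proportion.
    """
    off = pd.Timedelta(hours=local_offset_hr)

    def hour_month(ts: pd.Series):
        local = ts + off
        return local.dt.hour, local.dt.to_period("M").astype(str)

    matrices = {}

    def proportion_matrix(hours, months):
        df = pd.DataFrame({"hour": hours, "month": months})
        mat = df.groupby(["hour", "month"]).size().unstack(fill_value=0)
        mat = mat.reindex(index=range(24), fill_value=0).astype(float)
        colsum = mat.sum(axis=0)
        return mat / colsum.where(colsum > 0, np.nan)

    rep = labeled_dives[labeled_dives["klass"] == "repetitive"]
    deep = rep[rep["episode_median_depth_m"] > depth_split_m]
    shallow = rep[rep["episode_median_depth_m"] <= depth_split_m]
    mixed = labeled_dives[labeled_dives["klass"] == "mixed"]
    rest = episodes[episodes["klass"] == "resting"]
    for name, df, ts_col in (
        (f"repetitive_gt{depth_split_m:g}m", deep, "start"),
        (f"repetitive_le{depth_split_m:g}m", shallow, "start"),
        ("mixed", mixed, "start"),
        ("resting", rest, "start"),
    ):
        h, m = hour_month(df[ts_col]) if len(df) else (pd.Series(dtype=int), pd.Series(dtype=str))
        matrices[name] = proportion_matrix(h, m)

    if haulout_flags is not None:
        f = haulout_flags.copy()
        local = f["hour_start"] + off
        f["l_hour"] = local.dt.hour
        f["month"] = local.dt.to_period("M").astype(str)
        per_seal = (
            f.groupby(["seal_id", "month", "l_hour"])["haulout"].mean().rename("p").reset_index()
        )
        mean = per_seal.pivot_table(index="l_hour", columns="month", values="p", aggfunc="mean")
        se = per_seal.pivot_table(
            index="l_hour", columns="month", values="p",
            aggfunc=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        )
        matrices["haulout_mean"] = mean.reindex(index=range(24))
        matrices["haulout_se"] = se.reindex(index=range(24))
    return matrices


def bin_dive_histograms(
    dives: pd.DataFrame,
    depth_bins,
    period_hr: float = 6.0,
    local_offset_hr: float = -10.0,
    min_depth_m: float = 3.5,
) -> pd.DataFrame:
    """Counts of dives per depth bin per local-time block of the day.

    Depth bins follow the [lo, hi) convention; dives shallower than the
    histogram floor are excluded. Blocks partition the local day (e.g. four
    6-hr periods).
    """
    edges = np.asarray(depth_bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("depth bin edges must be ascending")
    d = dives[dives["max_depth_m"] >= min_depth_m].copy()
    local = d["start"] + pd.Timedelta(hours=local_offset_hr)
    d["period"] = (local.dt.hour // period_hr).astype(int) * int(period_hr)
    d["depth_bin"] = pd.cut(d["max_depth_m"], bins=edges, right=False)
    mat = (
        d.groupby(["depth_bin", "period"], observed=False).size().unstack(fill_value=0)
    )
    return mat


# ---------------------------------------------------------------------------
# depth-duration regression
# ---------------------------------------------------------------------------

def fit_depth_duration_curve(
    dives: pd.DataFrame,
    surfaces: pd.DataFrame | None = None,
    bin_width_m: float = 10.0,
    min_n: int = 10,
    max_duration_min: float = 15.0,
):
    """Logarithmic regressions of bin-median durations on bin-median depth.

    Dives longer than ``max_duration_min`` are excluded before binning into
    ``bin_width_m`` depth intervals; only bins holding >= ``min_n`` dives
    enter the OLS fit of median duration (and, when surface intervals are
    supplied, the median post-dive surface time) on ln(median depth). S is
    the residual standard error of the bin-level fit in minutes.

    Returns ``(dive_fit, surface_fit)``; ``surface_fit`` is None without
    surfaces.
    """
    d = dives.copy()
    d["duration_min"] = (d["end"] - d["start"]).dt.total_seconds() / 60.0
    d = d[d["duration_min"] <= max_duration_min]
    if surfaces is not None:
        # pair each dive with its following surface interval
        surf = surfaces.set_index(["seal_id", "start"])["duration_min"]
        key = pd.MultiIndex.from_arrays([d["seal_id"], d["end"]])
        d["surface_min"] = surf.reindex(key).values

    d["bin"] = (d["max_depth_m"] // bin_width_m) * bin_width_m
    g = d.groupby("bin")
    stats = g.agg(
        n=("max_depth_m", "size"),
        med_depth=("max_depth_m", "median"),
        med_dur=("duration_min", "median"),
    )
    if surfaces is not None:
        stats["med_surf"] = g["surface_min"].median()
    stats = stats[stats["n"] >= min_n]
    if len(stats) < 3:
        raise ValueError("need >= 3 qualifying depth bins")

    def ols(resp):
        X = sm.add_constant(np.log(stats["med_depth"].values))
        fit = sm.OLS(resp.values, X).fit()
        resid = resp.values - fit.predict(X)
        dof = max(len(resp) - 2, 1)
        s = float(np.sqrt(np.sum(resid**2) / dof))
        return DepthDurationFit(
            a=float(fit.params[0]), b=float(fit.params[1]), s=s,
            n_bins=len(stats), n_dives=int(stats["n"].sum()),
        )

    dive_fit = ols(stats["med_dur"])
    surf_fit = ols(stats["med_surf"].dropna()) if surfaces is not None else None
    return dive_fit, surf_fit
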