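"""Monthly activity budgets extrapolated from partially sampled sensors.

For each seal-month: the haul-out ratio (observed haul-out hours / observed
percent-dry hours) scales to the month's total hours; the remaining
non-haul-out hours are split between diving and surface resting by the time
ratio observed in the dive-behavior record (diving time includes surface
gaps <= 10 min inside dive episodes; resting time is surfaces > 10 min that
do not overlap a haul-out hour — overlapping ones were already counted as
haul-out and are discarded); diving hours are further split by the
repetitive : mixed episode-time ratio.

Inclusion filters mirror common biologging practice: a seal-month needs a
>= 10% sample of the dive-behavior stream and a mean distance to mainland
>= 5 km (near shore the water is often shallower than the tags' dive
 -detection threshold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EXCL_NO_DRY = "no_dry_data"
EXCL_SAMPLE = "insufficient_dive_sample"
EXCL_COAST = "near_shore"

BUDGET_COLUMNS = [
    "seal_id", "month", "month_hours", "sample_frac_dive", "sample_frac_dry",
    "haulout_h", "dive_h", "repetitive_h", "mixed_h", "rest_h",
    "diving_h_per_day", "repetitive_pct", "excluded", "reason",
]


def _month_bounds(month: str | pd.Period, span: tuple | None = None):
    """Month start/end, pro-rated to the deployment span when given."""
    p = pd.Period(month, freq="M")
    m0, m1 = p.start_time, (p + 1).start_time
    if span is not None:
        m0 = max(m0, pd.Timestamp(span[0]))
        m1 = min(m1, pd.Timestamp(span[1]))
    return m0, m1


def _overlap_hours(starts, ends, m0, m1) -> float:
    s = np.maximum(np.asarray(starts, dtype="datetime64[ns]"), np.datetime64(m0))
    e = np.minimum(np.asarray(ends, dtype="datetime64[ns]"), np.datetime64(m1))
    ov = (e - s) / np.timedelta64(1, "h")
    return float(np.sum(np.maximum(ov, 0.0)))


def monthly_sample_fraction(coverage: pd.DataFrame, drytimes: pd.DataFrame,
                            seal_id: str, month, span: tuple | None = None):
    """(frac_dive, frac_dry): sensor coverage of the (pro-rated) month.

    ``frac_dive`` is covered dive-record time over the month duration from
    the coverage windows; ``frac_dry`` is observed percent-dry hours over
    the month's hours.
    """
    m0, m1 = _month_bounds(month, span)
    month_h = (m1 - m0).total_seconds() / 3600.0
    if month_h <= 0:
        return 0.0, 0.0
    cov = coverage[coverage["seal_id"] == seal_id]
    frac_dive = _overlap_hours(cov["start"], cov["end"], m0, m1) / month_h if len(cov) else 0.0
    dry = drytimes[drytimes["seal_id"] == seal_id]
    hour_start = pd.to_datetime(dry["date"]) + pd.to_timedelta(dry["hour"], unit="h")
    n_obs = int(((hour_start >= m0) & (hour_start < m1)).sum())
    return frac_dive, n_obs / month_h


def extrapolate_monthly_budget(
    seal_id: str,
    month,
    haulout_flags: pd.DataFrame,
    episodes: pd.DataFrame,
    coverage: pd.DataFrame,
    habitat_days: pd.DataFrame | None = None,
    span: tuple | None = None,
    sample_min: float = 0.10,
    coast_excl_km: float = 5.0,
) -> dict:
    """One seal-month budget row (see BUDGET_COLUMNS) or an exclusion record.

    Components satisfy haulout_h + dive_h + rest_h == month hours exactly.
    """
    m0, m1 = _month_bounds(month, span)
    month_h = (m1 - m0).total_seconds() / 3600.0
    row = {c: np.nan for c in BUDGET_COLUMNS}
    row.update(seal_id=seal_id, month=str(pd.Period(month, freq="M")),
               month_hours=month_h, excluded=True, reason="")

    drytimes_like = haulout_flags[haulout_flags["seal_id"] == seal_id]
    in_month = (drytimes_like["hour_start"] >= m0) & (drytimes_like["hour_start"] < m1)
    obs = drytimes_like[in_month]
    frac_dry = len(obs) / month_h if month_h > 0 else 0.0
    cov = coverage[coverage["seal_id"] == seal_id]
    frac_dive = _overlap_hours(cov["start"], cov["end"], m0, m1) / month_h if month_h > 0 else 0.0
    row.update(sample_frac_dive=frac_dive, sample_frac_dry=frac_dry)

    if len(obs) == 0:
        row["reason"] = EXCL_NO_DRY
        return row
    if frac_dive < sample_min:
        row["reason"] = EXCL_SAMPLE
        return row
    if habitat_days is not None:
        hd = habitat_days[(habitat_days["seal_id"] == seal_id)]
        hd = hd[(hd["date"] >= m0.normalize()) & (hd["date"] < m1)]
        mean_coast = hd["dist_mainland_km"].mean()
        if np.isfinite(mean_coast) and mean_coast < coast_excl_km:
            row["reason"] = EXCL_COAST
            return row

    haulout_h = float(obs["haulout"].mean()) * month_h
    remaining = month_h - haulout_h

    eps = episodes[episodes["seal_id"] == seal_id]
    eps = eps[(eps["end"] > m0) & (eps["start"] < m1)]
    # tally only time the dive sensor was actually recording: a surface
    # spanning a sensor-off gap is unobserved, not resting
    windows = [
        (max(pd.Timestamp(w["start"]), m0), min(pd.Timestamp(w["end"]), m1))
        for _, w in cov.iterrows()
        if pd.Timestamp(w["end"]) > m0 and pd.Timestamp(w["start"]) < m1
    ]

    def class_hours(klass):
        sub = eps[eps["klass"] == klass]
        if klass == "resting":
            sub = sub[~sub.get("overlaps_haulout", pd.Series(False, index=sub.index)).fillna(False)]
        if sub.empty:
            return 0.0
        if not windows:
            return _overlap_hours(sub["start"], sub["end"], m0, m1)
        return sum(
            _overlap_hours(sub["start"], sub["end"], w0, w1) for (w0, w1) in windows
        )

    rep_t = class_hours("repetitive")
    mix_t = class_hours("mixed")
    rest_t = class_hours("resting")
    dive_t = rep_t + mix_t
    denom = dive_t + rest_t
    if denom <= 0:
        row["reason"] = "no_behavior_data"
        return row

    dive_h = remaining * dive_t / denom
    rest_h = remaining * rest_t / denom
    rep_h = dive_h * (rep_t / dive_t) if dive_t > 0 else 0.0
    mix_h = dive_h - rep_h
    days = month_h / 24.0
    row.update(
        haulout_h=haulout_h, dive_h=dive_h, repetitive_h=rep_h, mixed_h=mix_h,
        rest_h=rest_h, diving_h_per_day=dive_h / days if days > 0 else np.nan,
        repetitive_pct=100.0 * rep_h / dive_h if dive_h > 0 else np.nan,
        excluded=False, reason="",
    )
    return row


def monthly_budgets(
    haulout_flags: pd.DataFrame,
    episodes: pd.DataFrame,
    coverage: pd.DataFrame,
    habitat_days: pd.DataFrame | None = None,
    span: tuple | None = None,
    sample_min: float = 0.10,
    coast_excl_km: float = 5.0,
) -> pd.DataFrame:
    """All seal-months spanned by the inputs, one row each."""
    rows = []
    for sid in sorted(haulout_flags["seal_id"].unique()):
        f = haulout_flags[haulout_flags["seal_id"] == sid]
        months = pd.period_range(f["hour_start"].min(), f["hour_start"].max(), freq="M")
        for m in months:
            rows.append(
                extrapolate_monthly_budget(
                    sid, m, haulout_flags, episodes, coverage, habitat_days,
                    span=span, sample_min=sample_min, coast_excl_km=coast_excl_km,
                )
            )
    return pd.DataFrame(rows, columns=BUDGET_COLUMNS)


def budget_table(budgets: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-month mean +/- SD of diving h/day, repetitive %, sample %.

    Rows ordered by month with a pooled row over all included seal-months;
    an SD over a single seal-month is reported as 0 by convention.
    """
    inc = budgets[~budgets["excluded"].astype(bool)]
    if inc.empty:
        raise ValueError("no included seal-months")

    def summarize(df, label):
        sd = lambda v: float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return {
            "month": label,
            "n": len(df),
            "diving_h_mean": float(df["diving_h_per_day"].mean()),
            "diving_h_sd": sd(df["diving_h_per_day"]),
            "repetitive_pct_mean": float(df["repetitive_pct"].mean()),
            "repetitive_pct_sd": sd(df["repetitive_pct"]),
            "sample_pct_mean": float(100.0 * df["sample_frac_dive"].mean()),
            "sample_pct_sd": sd(100.0 * df["sample_frac_dive"]),
        }

    rows = [summarize(g, m) for m, g in inc.groupby("month", sort=True)]
    rows.append(summarize(inc, "pooled"))
    return pd.DataFrame(rows)
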