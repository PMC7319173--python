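"""Seeded truth-recovery experiments.

Each experiment simulates data with known ground truth, runs the relevant
pipeline stage, and measures recovery. They back the package's validation
suite and the reproduction script; problem sizes are chosen to give stable
medians on a single CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import budget as budget_mod
from . import divebehavior as db
from .simulate import SimConfig, simulate_dataset, simulate_track
from .track import fit_ctcrw, smooth_at_times

#: high-quality Argos mix for parameter-recovery runs: velocity-scale
#: parameters are only identifiable when location error is below the
#: per-step displacement scale (see docs/methods.md)
QUALITY_MIX = {"3": 0.4, "2": 0.4, "1": 0.2, "0": 0.0, "A": 0.0, "B": 0.0, "Z": 0.0}


def ctcrw_recovery(n_seeds: int = 20, beta: float = 1.0, sigma: float = 2.0,
                   span_days: int = 87, seed: int = 0) -> dict:
    """Refit beta/sigma on simulated tracks; check 95%-ellipse coverage.

    Each replicate simulates ~2,000 fixes (irregular ~0.5-hr gaps over
    ``span_days``), fits the CTCRW by maximum likelihood, and evaluates the
    smoother at the true-path times. Returns median absolute relative errors
    (percent) and pooled coverage of the 95% prediction ellipse.
    """
    beta_err, sigma_err, n_fixes = [], [], []
    hits = total = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=seed * 1000 + i, start="2016-07-01",
            end=str(pd.Timestamp("2016-07-01") + pd.Timedelta(days=span_days)),
            ou_beta=beta, ou_sigma=sigma, argos_class_probs=dict(QUALITY_MIX),
        )
        truth, fixes = simulate_track(cfg, 0)
        params = fit_ctcrw(fixes, proj=cfg.projection)
        beta_err.append(abs(params.beta - beta) / beta)
        sigma_err.append(abs(params.sigma - sigma) / sigma)
        n_fixes.append(len(fixes))
        t0 = fixes["timestamp"].min()
        hrs = (truth["timestamp"] - t0).dt.total_seconds().values / 3600.0
        sel = hrs >= 0
        mx, my, vx, vy = smooth_at_times(params, fixes, cfg.projection, hrs[sel])
        d2 = (
            (truth["x_km"].values[sel] - mx) ** 2 / np.maximum(vx, 1e-12)
            + (truth["y_km"].values[sel] - my) ** 2 / np.maximum(vy, 1e-12)
        )
        hits += int(np.sum(d2 <= chi2.ppf(0.95, 2)))
        total += int(sel.sum())
    return {
        "beta_median_abs_rel_err_pct": 100.0 * float(np.median(beta_err)),
        "sigma_median_abs_rel_err_pct": 100.0 * float(np.median(sigma_err)),
        "ellipse95_coverage_pct": 100.0 * hits / total,
        "median_n_fixes": float(np.median(n_fixes)),
    }


def run_budget_stage(bundle) -> pd.DataFrame:
    """Haul-out classification -> segmentation -> monthly extrapolation."""
    flags, _ = db.classify_haulout_hours(bundle.drytimes)
    surfaces = db.derive_surface_intervals(bundle.dives, flags)
    episodes = db.segment_behavior(bundle.dives, surfaces)
    episodes = db.flag_resting_overlaps(episodes, flags)
    return budget_mod.monthly_budgets(flags, episodes, bundle.coverage)


def budget_recovery(n_seeds: int = 20, n_seals: int = 4, coverage: float = 0.30,
                    seed: int = 0) -> dict:
    """Extrapolate monthly budgets at partial sensor coverage vs truth.

    Each replicate simulates a small cohort over one calendar month with
    ``coverage`` of both sensor streams observed, extrapolates, and compares
    haul-out and total diving hours against the planted schedule. The
    headline numbers are the across-replicate medians of the within-cohort
    median absolute relative errors, plus the worst conservation violation
    (component sum minus month hours).
    """
    h_err_seed, d_err_seed = [], []
    worst_conservation = 0.0
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=seed * 1000 + i, n_seals=n_seals,
            start="2016-07-01", end="2016-08-01",
            dive_coverage=coverage, dry_coverage=coverage,
        )
        bundle = simulate_dataset(cfg)
        budgets = run_budget_stage(bundle)
        truth = bundle.truth.budget.set_index(["seal_id", "month"])
        h_errs, d_errs = [], []
        for _, row in budgets[~budgets["excluded"].astype(bool)].iterrows():
            t = truth.loc[(row["seal_id"], row["month"])]
            true_dive = t["repetitive_h"] + t["mixed_h"]
            h_errs.append(abs(row["haulout_h"] - t["haulout_h"]) / t["haulout_h"])
            d_errs.append(abs(row["dive_h"] - true_dive) / true_dive)
            gap = abs(row["haulout_h"] + row["dive_h"] + row["rest_h"] - row["month_hours"])
            worst_conservation = max(worst_conservation, gap)
        h_err_seed.append(float(np.median(h_errs)))
        d_err_seed.append(float(np.median(d_errs)))
    return {
        "haulout_median_abs_rel_err_pct": 100.0 * float(np.median(h_err_seed)),
        "diving_median_abs_rel_err_pct": 100.0 * float(np.median(d_err_seed)),
        "max_conservation_err_hours": worst_conservation,
    }


def depth_duration_recovery(a: float = 2.0, b: float = 1.5) -> dict:
    """Noiseless recovery of the logarithmic depth-duration law."""
    rows = []
    t = pd.Timestamp("2016-07-01")
    for depth in range(15, 125, 10):
        for _ in range(12):
            dur = a + b * np.log(depth)
            rows.append(("s1", t, t + pd.Timedelta(minutes=dur), float(depth)))
            t += pd.Timedelta(minutes=20)
    dives = pd.DataFrame(rows, columns=["seal_id", "start", "end", "max_depth_m"])
    fit, _ = db.fit_depth_duration_curve(dives)
    return {"a": fit.a, "b": fit.b, "s_min": fit.s}
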