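"""Haul-out hours, surface intervals, dive-bout segmentation (including an
independent reference implementation of the classification rules), bottom
dives, diel profiles, histograms, and the depth-duration regression."""

import numpy as np
import pandas as pd
import pytest

from sealtracks import (
    bin_dive_histograms,
    classify_bottom_dive,
    classify_haulout_hours,
    derive_surface_intervals,
    diel_monthly_profiles,
    fit_depth_duration_curve,
    label_dives,
    segment_behavior,
)

from conftest import dive_frame


def dry_frame(percents, seal="s1", date="2016-07-01", start_hour=0):
    return pd.DataFrame(
        {
            "seal_id": seal,
            "date": pd.Timestamp(date),
            "hour": np.arange(start_hour, start_hour + len(percents)),
            "percent_dry": percents,
        }
    )


# ---------------------------------------------------------------------------
# haul-out hours
# ---------------------------------------------------------------------------

class TestHaulout:
    def test_threshold_boundary(self):
        flags, _ = classify_haulout_hours(dry_frame([80.0, 79.9]))
        assert flags["haulout"].tolist() == [True, False]

    def test_bout_run_lengths(self):
        flags, bouts = classify_haulout_hours(dry_frame([90, 95, 85, 10, 88]))
        assert sorted(bouts["duration_h"].tolist()) == [1, 3]

    def test_missing_hours_break_bouts(self):
        df = dry_frame([90, 90, 90])
        df = df[df["hour"] != 1]  # hour 1 unobserved
        _, bouts = classify_haulout_hours(df)
        assert bouts["duration_h"].tolist() == [1, 1]


# ---------------------------------------------------------------------------
# surface intervals
# ---------------------------------------------------------------------------

class TestSurfaceIntervals:
    def test_count_and_duration(self):
        dives = dive_frame([10, 12, 11], gaps_min=[0.7, 5.0])
        surf = derive_surface_intervals(dives)
        assert len(surf) == 2
        assert surf["duration_min"].iloc[0] == pytest.approx(0.7)

    def test_overlap_with_flagged_hour(self):
        dives = dive_frame([10, 12], gaps_min=[120.0], t0="2016-07-01 05:50")
        flags, _ = classify_haulout_hours(dry_frame([95.0], start_hour=6))
        surf = derive_surface_intervals(dives, flags)
        assert surf["overlaps_haulout"].iloc[0]

    def test_no_overlap_outside_flagged_hours(self):
        dives = dive_frame([10, 12], gaps_min=[30.0], t0="2016-07-01 12:00")
        flags, _ = classify_haulout_hours(dry_frame([95.0], start_hour=6))
        surf = derive_surface_intervals(dives, flags)
        assert not surf["overlaps_haulout"].iloc[0]


# ---------------------------------------------------------------------------
# segmentation: worked examples
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_five_similar_dives_one_repetitive_episode(self):
        eps = segment_behavior(dive_frame([100, 101, 99, 100, 102]))
        assert eps["klass"].tolist() == ["repetitive"]
        assert eps["n_dives"].iloc[0] == 5

    def test_single_deviant_dive_allowed_within_episode(self):
        eps = segment_behavior(dive_frame([60, 62, 61, 300, 60, 63, 59]))
        assert eps["klass"].tolist() == ["repetitive"]
        assert eps["n_dives"].iloc[0] == 7

    def test_four_matched_dives_stay_mixed(self):
        eps = segment_behavior(dive_frame([50, 51, 50, 52]))
        assert eps["klass"].tolist() == ["mixed"]

    def test_two_consecutive_deviants_close_the_episode(self):
        eps = segment_behavior(dive_frame([100, 101, 99, 100, 102, 300, 20, 100]))
        assert eps[eps["klass"] == "repetitive"]["n_dives"].iloc[0] == 5

    def test_long_surface_splits_into_resting(self):
        dives = dive_frame([100, 101, 99, 100, 102] * 2,
                           gaps_min=[1, 1, 1, 1, 25, 1, 1, 1, 1])
        eps = segment_behavior(dives)
        klasses = eps["klass"].tolist()
        assert klasses.count("repetitive") == 2
        assert klasses.count("resting") == 1

    def test_every_dive_in_exactly_one_episode(self):
        rng = np.random.default_rng(5)
        depths = rng.uniform(5, 200, 40).round(1)
        gaps = rng.uniform(0.5, 20, 39)
        dives = dive_frame(depths, gaps_min=gaps)
        eps = segment_behavior(dives)
        diveful = eps[eps["klass"] != "resting"]
        covered = []
        for _, r in diveful.iterrows():
            covered.extend(range(int(r["dive_index_start"]), int(r["dive_index_end"]) + 1))
        assert sorted(covered) == list(range(len(dives)))
        assert (eps[eps["klass"] == "repetitive"]["n_dives"] >= 5).all()
        # no two adjacent resting episodes
        rest_flags = (eps.sort_values("start")["klass"] == "resting").tolist()
        assert not any(a and b for a, b in zip(rest_flags, rest_flags[1:]))


# ---------------------------------------------------------------------------
# segmentation: reference-implementation equivalence
# ---------------------------------------------------------------------------

def reference_segmentation(depths, gaps_min, rest_min=10.0, tol=0.15,
                           rep_min=5, min_denom=2.0):
    """Plain-loop transliteration of the classification rules.

    Returns per-dive labels plus the indices of resting gaps, built with
    explicit list scanning rather than the package's vectorized flag/cut
    arrays.
    """
    n = len(depths)
    labels = ["mixed"] * n
    # split indices into segments at long surfaces
    segments, cur = [], [0]
    for i, g in enumerate(gaps_min):
        if g > rest_min:
            segments.append(cur)
            cur = [i + 1]
        else:
            cur.append(i + 1)
    segments.append(cur)

    for seg in segments:
        m = len(seg)
        flag = {}
        for pos in range(1, m):
            ok = False
            for back in (1, 2):
                if pos - back >= 0:
                    ref = depths[seg[pos - back]]
                    if abs(depths[seg[pos]] - ref) <= tol * max(ref, min_denom):
                        ok = True
            flag[pos] = ok
        # chains: walk and break where an inconsistent transition is adjacent
        # to another inconsistent transition
        chains, chain = [], [0]
        for pos in range(1, m):
            bad = not flag[pos]
            prev_bad = pos - 1 >= 1 and not flag[pos - 1]
            next_bad = pos + 1 < m and not flag[pos + 1]
            if bad and (prev_bad or next_bad):
                chains.append(chain)
                chain = [pos]
            else:
                chain.append(pos)
        chains.append(chain)
        for chain in chains:
            # peel trailing inconsistent members
            while len(chain) > 1 and not flag[chain[-1]]:
                chain = chain[:-1]
            good = sum(1 for pos in chain if pos == chain[0] or flag[pos])
            if good >= rep_min:
                for pos in chain:
                    labels[seg[pos]] = "repetitive"
    resting_gaps = [i for i, g in enumerate(gaps_min) if g > rest_min]
    return labels, resting_gaps


def package_labels(dives):
    eps = segment_behavior(dives)
    lab = label_dives(dives, eps)
    resting = eps[eps["klass"] == "resting"]
    starts = dives.sort_values("start").reset_index(drop=True)["start"]
    rest_idx = [int(starts.searchsorted(r["end"]) - 1) for _, r in resting.iterrows()]
    return lab["klass"].tolist(), sorted(rest_idx)


def test_segmentation_matches_reference_on_random_sequences():
    """Exhaustive cross-check on 1,000 random short dive sequences."""
    rng = np.random.default_rng(2024)
    for trial in range(1000):
        n = int(rng.integers(1, 13))
        # depths drawn coarsely so near-tolerance ties arise often
        depths = rng.choice([5, 10, 11, 12, 14, 20, 50, 55, 60, 100, 110, 300], size=n).astype(float)
        gaps = rng.choice([0.5, 2.0, 9.9, 10.1, 30.0], size=max(n - 1, 0))
        dives = dive_frame(depths, gaps_min=gaps)
        got_labels, got_rest = package_labels(dives)
        want_labels, want_rest = reference_segmentation(list(depths), list(gaps))
        assert got_labels == want_labels, (
            f"trial {trial}: depths={depths.tolist()} gaps={gaps.tolist()} "
            f"got={got_labels} want={want_labels}"
        )
        assert got_rest == want_rest, f"trial {trial}: resting gaps differ"


# ---------------------------------------------------------------------------
# bottom dives
# ---------------------------------------------------------------------------

class TestBottomDive:
    @pytest.mark.parametrize(
        "depth,ocean,expect",
        [
            (75.0, 100.0, "bottom"),
            (74.9, 100.0, "pelagic"),
            (120.0, 100.0, "bottom"),  # implausible excess still counts
            (5.0, 9.0, "indeterminate"),
            (5.0, np.nan, "indeterminate"),
        ],
    )
    def test_rule(self, depth, ocean, expect):
        assert classify_bottom_dive(depth, ocean) == expect

    def test_monotone_in_dive_depth(self):
        depths = np.linspace(1, 200, 400)
        calls = classify_bottom_dive(depths, np.full_like(depths, 100.0))
        order = {"pelagic": 0, "bottom": 1}
        ranks = [order[c] for c in calls]
        assert ranks == sorted(ranks)


# ---------------------------------------------------------------------------
# diel profiles
# ---------------------------------------------------------------------------

class TestDielProfiles:
    def test_all_events_at_one_local_hour(self):
        # 13:00 UTC == 03:00 local at UTC-10
        dives = dive_frame([100] * 6, gaps_min=[1] * 5, t0="2016-07-03 13:00")
        eps = segment_behavior(dives)
        lab = label_dives(dives, eps)
        mats = diel_monthly_profiles(lab, eps)
        deep = mats["repetitive_gt25m"]
        assert deep.loc[3, "2016-07"] == pytest.approx(1.0)
        assert deep.drop(index=3)["2016-07"].sum() == pytest.approx(0.0)

    def test_monthly_columns_sum_to_one(self):
        rng = np.random.default_rng(8)
        dives = dive_frame(rng.uniform(5, 150, 200).round(0),
                           gaps_min=rng.uniform(0.5, 30, 199))
        eps = segment_behavior(dives)
        lab = label_dives(dives, eps)
        mats = diel_monthly_profiles(lab, eps)
        for name, mat in mats.items():
            for col in mat.columns:
                if mat[col].notna().any():
                    assert mat[col].sum() == pytest.approx(1.0)

    def test_haulout_matrix_mean_and_se(self):
        flags_a = dry_frame([90.0] * 24, seal="a")
        flags_b = dry_frame([10.0] * 24, seal="b")
        flags, _ = classify_haulout_hours(pd.concat([flags_a, flags_b], ignore_index=True))
        empty = dive_frame([100] * 5)
        eps = segment_behavior(empty)
        lab = label_dives(empty, eps)
        mats = diel_monthly_profiles(lab, eps, haulout_flags=flags)
        # one seal always hauled, one never: mean 0.5 everywhere observed
        mean = mats["haulout_mean"].dropna(how="all")
        assert np.allclose(mean.dropna().values, 0.5)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

class TestHistograms:
    def test_single_dive_counted_once(self):
        mat = bin_dive_histograms(dive_frame([40.0]), [0, 50, 100])
        assert mat.values.sum() == 1

    def test_bin_edge_goes_to_lower_bin(self):
        mat = bin_dive_histograms(dive_frame([50.0]), [0, 50, 100])
        bins = [str(b) for b in mat.index]
        row = mat.sum(axis=1)
        assert row[[("50" in b and "100" in b) for b in bins]].iloc[0] == 1

    def test_conservation_and_floor(self):
        depths = [2.0, 3.4, 3.5, 10.0, 49.9, 50.0, 120.0]
        dives = dive_frame(depths, gaps_min=[1] * 6)
        mat = bin_dive_histograms(dives, [0, 50, 100, 200], min_depth_m=3.5)
        assert mat.values.sum() == sum(d >= 3.5 for d in depths)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_dive_histograms(dive_frame([10.0]), [50, 0])


# ---------------------------------------------------------------------------
# depth-duration regression
# ---------------------------------------------------------------------------

def synth_logcurve_dives(a=2.0, b=1.5, n_per_bin=12, depths=None):
    depths = depths or [15, 25, 35, 45, 55, 65, 75]
    rows = []
    t = pd.Timestamp("2016-07-01")
    for d in depths:
        for _ in range(n_per_bin):
            dur = a + b * np.log(d)
            rows.append((t, t + pd.Timedelta(minutes=dur), float(d)))
            t += pd.Timedelta(minutes=20)
    return pd.DataFrame(
        {"seal_id": "s1", "start": [r[0] for r in rows],
         "end": [r[1] for r in rows], "max_depth_m": [r[2] for r in rows]}
    )


class TestDepthDuration:
    def test_noiseless_recovery_exact(self):
        dives = synth_logcurve_dives(a=2.0, b=1.5)
        fit, _ = fit_depth_duration_curve(dives)
        assert fit.a == pytest.approx(2.0, abs=1e-8)
        assert fit.b == pytest.approx(1.5, abs=1e-8)
        assert fit.s == pytest.approx(0.0, abs=1e-8)

    def test_sparse_bins_excluded(self):
        dives = synth_logcurve_dives(n_per_bin=12)
        extra = dive_frame([200.0] * 3, gaps_min=[1, 1], t0="2016-08-01")
        fit, _ = fit_depth_duration_curve(pd.concat([dives, extra], ignore_index=True))
        assert fit.n_bins == 7  # the 3-dive 200-m bin does not qualify

    def test_long_dives_excluded_before_binning(self):
        dives = synth_logcurve_dives()
        slow = dive_frame([30.0] * 30, gaps_min=[1] * 29, t0="2016-08-01", dur_min=20.0)
        fit, _ = fit_depth_duration_curve(pd.concat([dives, slow], ignore_index=True))
        assert fit.a == pytest.approx(2.0, abs=1e-8)  # 20-min dives never entered

    def test_surface_regression_paired_with_following_interval(self):
        dives = synth_logcurve_dives(a=1.0, b=0.5)
        surf = derive_surface_intervals(dives)
        _, sfit = fit_depth_duration_curve(dives, surfaces=surf)
        assert sfit is not None and np.isfinite(sfit.a)

    def test_too_few_bins_raises(self):
        dives = synth_logcurve_dives(depths=[15, 25])
        with pytest.raises(ValueError, match=">= 3"):
            fit_depth_duration_curve(dives)
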