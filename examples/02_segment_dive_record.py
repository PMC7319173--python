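"""Segment a dive record into resting / repetitive / mixed episodes.

Simulates one week of dive and wet/dry data with a planted behavior
schedule, classifies haul-out hours (>= 80% dry), segments the dive series,
and fits the logarithmic depth-duration curve.
"""

import sealtracks as st

cfg = st.SimConfig(seed=7, start="2016-07-01", end="2016-07-08",
                   dive_coverage=1.0, dry_coverage=1.0)
bundle = st.simulate_dataset(cfg)
print(f"{len(bundle.dives)} dives, {len(bundle.drytimes)} hourly percent-dry values")

flags, bouts = st.classify_haulout_hours(bundle.drytimes, threshold=80.0)
print(f"haul-out hours: {int(flags['haulout'].sum())} in {len(bouts)} bouts "
      f"(median bout {bouts['duration_h'].median():.0f} hr)")

surfaces = st.derive_surface_intervals(bundle.dives, flags)
episodes = st.segment_behavior(bundle.dives, surfaces)
counts = episodes["klass"].value_counts().to_dict()
print(f"episodes: {counts}")
rep = episodes[episodes["klass"] == "repetitive"]
print(f"repetitive episodes hold {rep['n_dives'].sum()} dives "
      f"(median depth {rep['median_depth_m'].median():.0f} m)")

fit, surf_fit = st.fit_depth_duration_curve(bundle.dives, surfaces)
print(f"dive duration = {fit.a:.2f} + {fit.b:.2f} ln(depth) min, S = {fit.s:.2f} min "
      f"({fit.n_bins} depth bins, {fit.n_dives} dives)")
# Repetitive episodes (>= 5 sequential dives to depths within +/-15%) are the
# putative foraging mode; the depth-duration slope shows dives lengthening
# roughly logarithmically with depth.
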