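"""Analysis configuration: every threshold of the pipeline as a named field.

Thresholds live here once and flow to each stage; the full config is
serialized into the run manifest so outputs are reproducible from the
manifest alone. Timestamps are ISO-8601 UTC everywhere; local time (fixed
UTC-10 for the study region) appears only in diel presentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    # haul-out / behavior
    dry_threshold: float = 80.0        # % dry for a haul-out hour
    rest_surface_min: float = 10.0     # min; surfaces longer are resting
    rep_min_dives: int = 5
    rep_tol: float = 0.15              # +/- depth tolerance for repetitive diving
    min_denom_depth: float = 2.0       # m; guards the tolerance denominator
    bottom_frac: float = 0.75          # dive depth / ocean depth for a bottom dive
    min_bottom_ocean_depth: float = 10.0
    dive_floor_m: float = 3.5          # histogram detection floor
    depth_split_m: float = 25.0        # diel split of repetitive episodes
    # zones / habitat
    shelf_max: float = 300.0           # m
    basin_min: float = 1000.0          # m
    ice_radius: float = 50.0           # km, mean-concentration disc
    ice_edge_conc: float = 15.0        # %
    ice_edge_min_pixels: int = 10
    bridge_break_days: int = 1
    # track
    se_max: float = 25.0               # km, drop CTCRW estimates above this
    grid_step: float = 6.0             # hr
    max_speed: float = 10.0            # km/hr plausibility filter
    spike_angle: float = 15.0          # degrees
    spike_speed: float = 5.0           # km/hr
    # budget
    coast_excl: float = 5.0            # km, seal-month exclusion
    sample_min: float = 0.10           # min dive-stream sample fraction
    first_week_excluded: bool = True
    # presentation
    local_offset: float = -10.0        # hr from UTC

    def __post_init__(self):
        positive = ["dry_threshold", "rest_surface_min", "rep_tol", "bottom_frac",
                    "shelf_max", "basin_min", "se_max", "ice_radius", "ice_edge_conc",
                    "coast_excl", "sample_min", "grid_step", "max_speed"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.dry_threshold <= 100:
            raise ValueError("dry_threshold must be in (0, 100]")
        if self.basin_min <= self.shelf_max:
            raise ValueError("basin_min must exceed shelf_max")
        if self.rep_min_dives < 2:
            raise ValueError("rep_min_dives must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
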