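import numpy as np
import pandas as pd
import pytest
import xarray as xr

from sealtracks import SimConfig, simulate_dataset
from sealtracks.rasters import make_grid


@pytest.fixture(scope="session")
def week_bundle():
    """One seal, one week, full sensor coverage: the workhorse fixture."""
    cfg = SimConfig(
        seed=11, n_seals=1, start="2016-07-01", end="2016-07-08",
        dive_coverage=1.0, dry_coverage=1.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def small_grid():
    """10x10 25-km grid with a southern land strip (rows 0-1) and uniform sea."""
    g = make_grid(10, 25.0, -170.0, 70.0)
    land = np.zeros((10, 10), dtype=np.int8)
    land[:2, :] = 1
    depth = np.full((10, 10), 100.0)
    depth[land.astype(bool)] = np.nan
    g["land"] = (("y", "x"), land)
    g["depth"] = (("y", "x"), depth)
    return g


def ice_on(grid: xr.Dataset, conc: np.ndarray) -> xr.Dataset:
    """Attach a 2-D concentration field (NaN over land) to a grid."""
    g = grid.copy()
    field = np.where(grid["land"].values.astype(bool), np.nan, conc)
    g["ice_conc"] = (("y", "x"), field)
    return g


def dive_frame(depths, gaps_min=None, t0="2016-07-01 00:00", dur_min=3.0, seal="s1"):
    """Build a dive table from a depth sequence and surface gaps (minutes)."""
    n = len(depths)
    gaps = [1.0] * (n - 1) if gaps_min is None else list(gaps_min)
    starts, ends = [], []
    t = pd.Timestamp(t0)
    for i, d in enumerate(depths):
        starts.append(t)
        t = t + pd.Timedelta(minutes=dur_min)
        ends.append(t)
        if i < n - 1:
            t = t + pd.Timedelta(minutes=gaps[i])
    return pd.DataFrame(
        {"seal_id": seal, "start": starts, "end": ends, "max_depth_m": list(depths)}
    )
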