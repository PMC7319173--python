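"""Raster containers and I/O on the 25-km equal-area analysis grid.

Bathymetry/land and daily sea-ice concentration are carried as xarray
Datasets on a shared planar grid (coordinates ``x``/``y`` in km of the
study's equal-area projection). Every grid stores 2-D ``lon``/``lat`` cell
centers so habitat metrics can use great-circle distances.

Conventions
-----------
bathymetry Dataset:
    ``depth``  (y, x) float, ocean depth in m, NaN over land
    ``land``   (y, x) int8, 1 = land cell
ice Dataset:
    ``ice_conc`` (time, y, x) float, percent 0-100, NaN over land
Attributes on both: ``center_lon``, ``center_lat``, ``cell_km``.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .projection import LambertAzimuthalEqualArea

DEFAULT_CELL_KM = 25.0


def make_grid(n_cells: int, cell_km: float, center_lon: float, center_lat: float) -> xr.Dataset:
    """Empty n x n grid centered on the projection origin.

    Cell centers run symmetrically about 0 with spacing ``cell_km``.
    """
    half = n_cells * cell_km / 2.0
    coords = np.arange(n_cells) * cell_km - half + cell_km / 2.0
    xx, yy = np.meshgrid(coords, coords)
    proj = LambertAzimuthalEqualArea(center_lon, center_lat)
    lon, lat = proj.inverse(xx, yy)
    ds = xr.Dataset(
        coords={"x": ("x", coords), "y": ("y", coords)},
        data_vars={
            "lon": (("y", "x"), lon),
            "lat": (("y", "x"), lat),
        },
        attrs={"center_lon": center_lon, "center_lat": center_lat, "cell_km": cell_km},
    )
    return ds


def grid_projection(ds: xr.Dataset) -> LambertAzimuthalEqualArea:
    return LambertAzimuthalEqualArea(float(ds.attrs["center_lon"]), float(ds.attrs["center_lat"]))


def nearest_cell_index(ds: xr.Dataset, x_km: float, y_km: float) -> tuple[int, int]:
    """(row, col) of the grid cell whose center is nearest the point."""
    iy = int(np.argmin(np.abs(ds["y"].values - y_km)))
    ix = int(np.argmin(np.abs(ds["x"].values - x_km)))
    return iy, ix


def point_in_grid(ds: xr.Dataset, x_km: float, y_km: float) -> bool:
    half = float(ds.attrs["cell_km"]) / 2.0
    return (
        ds["x"].values.min() - half <= x_km <= ds["x"].values.max() + half
        and ds["y"].values.min() - half <= y_km <= ds["y"].values.max() + half
    )


def write_netcdf(ds: xr.Dataset, path) -> None:
    """Write via the NetCDF3 (scipy) backend; int8/float only."""
    enc = {v: {"dtype": "int8"} for v in ds.data_vars if ds[v].dtype == bool}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def open_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()
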