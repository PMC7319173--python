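"""Lambert azimuthal equal-area projection and great-circle distances.

Track modelling is done in a planar equal-area frame (km) centered on the
study area; habitat distances are great-circle on the sphere. A spherical
earth with the IUGG mean radius is used throughout, which keeps forward and
inverse transforms exactly closed-form and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class LambertAzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection.

    Parameters
    ----------
    center_lon, center_lat : float
        Projection center in decimal degrees. Forward maps the center to
        (0, 0); coordinates are in kilometres.
    """

    center_lon: float
    center_lat: float

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to x/y (km). Arrays broadcast."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lam0 = np.radians(self.center_lon)
        phi0 = np.radians(self.center_lat)
        lam = np.radians(lon)
        phi = np.radians(lat)
        dlam = lam - lam0
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        if np.any(denom < 1e-12):
            raise ValueError("point is antipodal to the projection center")
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        """Unproject x/y (km) back to lon/lat (degrees)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lam0 = np.radians(self.center_lon)
        phi0 = np.radians(self.center_lat)
        rho = np.hypot(x, y)
        # rho == 0 maps to the center; guard the division.
        rho_safe = np.where(rho == 0.0, 1.0, rho)
        arg = rho / (2.0 * EARTH_RADIUS_KM)
        if np.any(arg > 1.0):
            raise ValueError("point outside the projection's valid disc")
        c = 2.0 * np.arcsin(arg)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(
            cos_c * np.sin(phi0) + (y / rho_safe) * sin_c * np.cos(phi0)
        )
        lam = lam0 + np.arctan2(
            x * sin_c,
            rho_safe * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c,
        )
        lon = np.degrees(np.where(rho == 0.0, lam0, lam))
        lat = np.degrees(np.where(rho == 0.0, phi0, phi))
        # normalize longitudes to (-180, 180]
        lon = (lon + 180.0) % 360.0 - 180.0
        return lon, lat


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
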