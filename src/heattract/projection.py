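"""Equal-area map projection used for planar distance computations.

Nearest-neighbor lookups and inverse-distance weights are computed on
projected coordinates.  An Albers equal-area conic on the authalic sphere is
used; its standard parallels default to the 1/6 rule over the domain's
latitude span, so the projection adapts to whatever region the grid covers.
"""

from __future__ import annotations

import numpy as np

#: Authalic Earth radius [m].
EARTH_RADIUS = 6371007.2


class AlbersEqualArea:
    """Albers equal-area conic projection (spherical form).

    Parameters
    ----------
    lat0, lon0 : float
        Latitude / longitude of origin, degrees.
    lat1, lat2 : float
        Standard parallels, degrees.  Must not be opposite.
    """

    def __init__(self, lat0: float, lon0: float, lat1: float, lat2: float):
        if abs(lat1 + lat2) < 1e-12 and abs(lat1) > 1e-12:
            raise ValueError("standard parallels may not be opposite")
        self.lat0, self.lon0 = float(lat0), float(lon0)
        self.lat1, self.lat2 = float(lat1), float(lat2)
        phi0, phi1, phi2 = np.radians([lat0, lat1, lat2])
        self._n = 0.5 * (np.sin(phi1) + np.sin(phi2))
        if abs(self._n) < 1e-12:
            raise ValueError("degenerate cone constant; choose other parallels")
        self._C = np.cos(phi1) ** 2 + 2.0 * self._n * np.sin(phi1)
        self._rho0 = EARTH_RADIUS * np.sqrt(self._C - 2.0 * self._n * np.sin(phi0)) / self._n

    @classmethod
    def for_domain(cls, lat: np.ndarray, lon: np.ndarray) -> "AlbersEqualArea":
        """Projection centered on the bounding box of (lat, lon) points."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        lat_min, lat_max = float(lat.min()), float(lat.max())
        span = max(lat_max - lat_min, 1.0)
        return cls(
            lat0=0.5 * (lat_min + lat_max),
            lon0=0.5 * (float(lon.min()) + float(lon.max())),
            lat1=lat_min + span / 6.0,
            lat2=lat_max - span / 6.0,
        )

    def forward(self, lat, lon):
        """Project degrees -> (x, y) meters."""
        phi = np.radians(np.asarray(lat, dtype=float))
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        rho = EARTH_RADIUS * np.sqrt(self._C - 2.0 * self._n * np.sin(phi)) / self._n
        theta = self._n * lam
        return rho * np.sin(theta), self._rho0 - rho * np.cos(theta)

    def xy(self, lat, lon) -> np.ndarray:
        """Projected coordinates stacked as an (n, 2) array."""
        x, y = self.forward(lat, lon)
        return np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
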