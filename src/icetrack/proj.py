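"""Planar projection helpers.

Movement metrics (speeds, step lengths, kernel densities) are computed on a
projected plane.  For high-Arctic work the natural choice is a north polar
stereographic projection; the spherical-datum formulas below are accurate to
well under 0.5 % at the latitudes of interest, which is ample for movement
metrics dominated by Argos error.  All distances are in metres.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def project(lon, lat, lon0: float = 0.0, lat_ts: float = 71.0):
    """North polar stereographic forward projection (spherical datum).

    Parameters
    ----------
    lon, lat : array_like
        Geographic coordinates in degrees.
    lon0 : float
        Central meridian (degrees east).
    lat_ts : float
        Latitude of true scale (degrees north).

    Returns
    -------
    x, y : ndarray
        Projected coordinates in metres; the pole maps to (0, 0) and ``y``
        decreases along ``lon0``.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    k0 = (1.0 + np.sin(np.radians(lat_ts))) / 2.0
    rho = 2.0 * EARTH_RADIUS_M * k0 * np.tan(np.pi / 4.0 - lat / 2.0)
    dlon = lon - np.radians(lon0)
    return rho * np.sin(dlon), -rho * np.cos(dlon)


def unproject(x, y, lon0: float = 0.0, lat_ts: float = 71.0):
    """Inverse of :func:`project`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k0 = (1.0 + np.sin(np.radians(lat_ts))) / 2.0
    rho = np.hypot(x, y)
    lat = np.pi / 2.0 - 2.0 * np.arctan(rho / (2.0 * EARTH_RADIUS_M * k0))
    lon = np.radians(lon0) + np.arctan2(x, -y)
    return np.degrees(lon), np.degrees(lat)
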