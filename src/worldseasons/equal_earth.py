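"""The Equal Earth pseudocylindrical equal-area projection.

Closed-form forward mapping and an iterative (Newton) inverse on the WGS84
authalic sphere, matching EPSG:8857.  The projection is defined through an
auxiliary latitude theta with ``sin(theta) = (sqrt(3)/2) sin(lat)`` and a
9th-degree odd polynomial in theta for the northing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["equal_earth_forward", "equal_earth_inverse", "EARTH_RADIUS_AUTHALIC"]

#: WGS84 authalic sphere radius, metres
EARTH_RADIUS_AUTHALIC = 6_371_007.181

_A1 = 1.340264
_A2 = -0.081106
_A3 = 0.000893
_A4 = 0.003796
_M = np.sqrt(3.0) / 2.0


def _poly(theta: np.ndarray) -> np.ndarray:
    t2 = theta * theta
    return theta * (_A1 + _A2 * t2 + t2 ** 3 * (_A3 + _A4 * t2))


def _dpoly(theta: np.ndarray) -> np.ndarray:
    t2 = theta * theta
    return _A1 + 3 * _A2 * t2 + t2 ** 3 * (7 * _A3 + 9 * _A4 * t2)


def equal_earth_forward(lon_deg, lat_deg, radius: float = EARTH_RADIUS_AUTHALIC):
    """Project lon/lat in degrees to Equal Earth (x, y) in metres."""
    lam = np.radians(np.asarray(lon_deg, dtype=float))
    phi = np.radians(np.asarray(lat_deg, dtype=float))
    theta = np.arcsin(np.clip(_M * np.sin(phi), -1.0, 1.0))
    x = radius * (2.0 * np.sqrt(3.0) / 3.0) * lam * np.cos(theta) / _dpoly(theta)
    y = radius * _poly(theta)
    return x, y


def equal_earth_inverse(x, y, radius: float = EARTH_RADIUS_AUTHALIC):
    """Invert Equal Earth (x, y) in metres to lon/lat in degrees.

    Points whose northing lies outside the projection's range come back NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    target = y / radius
    theta = np.array(target / _A1, dtype=float)  # good starting guess
    for _ in range(30):
        delta = (_poly(theta) - target) / _dpoly(theta)
        theta = theta - delta
        if np.all(np.abs(delta) < 1e-12):
            break
    bad = np.abs(theta) > np.pi / 2
    theta = np.where(bad, np.nan, theta)
    sin_phi = np.sin(theta) / _M
    phi = np.arcsin(np.clip(sin_phi, -1.0, 1.0))
    phi = np.where(np.abs(sin_phi) > 1 + 1e-9, np.nan, phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = x * _dpoly(theta) / (radius * (2.0 * np.sqrt(3.0) / 3.0) * np.cos(theta))
    lon = np.degrees(lam)
    lon = np.where(np.abs(lon) > 180 + 1e-6, np.nan, lon)
    return lon, np.degrees(phi)
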