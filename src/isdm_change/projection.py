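"""Lambert azimuthal equal-area projection on the authalic sphere.

The analysis grid lives in a planar LAEA coordinate system (kilometres)
centred, by default, on latitude 0° and longitude −73.125° so that square
grid cells have constant true area across the study extent. The spherical
form is used (authalic radius 6371.0072 km); over a continental extent the
difference from the ellipsoidal projection is far below the 100-km grain
of the analysis.
"""

from __future__ import annotations

import numpy as np

#: Authalic Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0072

#: Default projection centre (lat, lon) in decimal degrees.
DEFAULT_CENTER = (0.0, -73.125)


def laea_forward(
    lon: np.ndarray,
    lat: np.ndarray,
    center: tuple[float, float] = DEFAULT_CENTER,
    radius_km: float = EARTH_RADIUS_KM,
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to planar LAEA x/y in kilometres.

    Points antipodal to the projection centre are mapped to NaN.
    """
    lat0, lon0 = center
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = np.radians(lat0)

    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = radius_km * np.sqrt(np.where(denom > 0, 2.0 / denom, np.nan))
    x = k * np.cos(phi) * np.sin(lam)
    y = k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def laea_inverse(
    x: np.ndarray,
    y: np.ndarray,
    center: tuple[float, float] = DEFAULT_CENTER,
    radius_km: float = EARTH_RADIUS_KM,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse projection: planar km back to lon/lat in degrees."""
    lat0, lon0 = center
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0 = np.radians(lat0)

    rho = np.hypot(x, y)
    # Angular distance from the projection centre.
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * radius_km), -1.0, 1.0))
    sin_c, cos_c = np.sin(c), np.cos(c)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(
            rho > 0,
            np.arcsin(np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / np.where(rho > 0, rho, 1.0), -1.0, 1.0)),
            phi0,
        )
        lam = np.where(
            rho > 0,
            np.arctan2(x * sin_c, rho * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c),
            0.0,
        )
    return np.degrees(lam) + lon0, np.degrees(phi)
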