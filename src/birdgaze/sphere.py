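"""Spherical chart shared by every module that talks about viewing directions.

The camera/visual frame convention is: y = forward (gaze), x = right,
z = dorsal (up); right-handed.  Longitude ``lon`` in [-180, 180) degrees is
positive toward +x (the animal's right); latitude ``lat`` in [-90, +90]
is positive toward +z.  The forward direction is ``direction(0, 0) = (0,1,0)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["direction_from_lonlat", "lonlat_from_direction", "wrap_longitude"]


def direction_from_lonlat(lon_deg, lat_deg) -> np.ndarray:
    """Unit direction(s) for longitude/latitude in degrees; shape (...,3)."""
    lon, lat = np.broadcast_arrays(
        np.deg2rad(np.asarray(lon_deg, dtype=float)),
        np.deg2rad(np.asarray(lat_deg, dtype=float)),
    )
    cos_lat = np.cos(lat)
    return np.stack(
        [np.sin(lon) * cos_lat, np.cos(lon) * cos_lat, np.sin(lat)], axis=-1
    )


def lonlat_from_direction(d) -> tuple[np.ndarray, np.ndarray]:
    """Longitude, latitude in degrees for direction(s) (...,3); not necessarily unit."""
    d = np.asarray(d, dtype=float)
    lon = np.degrees(np.arctan2(d[..., 0], d[..., 1]))
    lat = np.degrees(np.arctan2(d[..., 2], np.hypot(d[..., 0], d[..., 1])))
    return lon, lat


def wrap_longitude(lon_deg):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon_deg, dtype=float) + 180.0) % 360.0 - 180.0
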