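"""Equirectangular spherical camera grid.

The 360° virtual camera samples the sphere of viewing directions uniformly
in longitude and latitude (default 5 pixels per degree).  Pixel centres sit
at half-integer offsets; the image centre is the forward direction
(longitude 0, latitude 0).  Because the chart is equirectangular, pixels
subtend latitude-dependent solid angles; the per-pixel solid angle A (and
its normalised form A_i = A / max A) weights every statistic computed on
the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere import direction_from_lonlat

__all__ = ["CameraGrid", "orthographic_view"]


@dataclass
class CameraGrid:
    """Pixel↔direction chart for an equirectangular spherical camera.

    ``resolution`` is in pixels per degree; the raster is
    (180*R) rows x (360*R) columns, row 0 at the north (dorsal) pole,
    column 0 at longitude -180°.
    """

    resolution: float = 5.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.width = int(round(360 * self.resolution))
        self.height = int(round(180 * self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_longitudes(self) -> np.ndarray:
        """Longitude (deg) of each column's pixel centres."""
        return -180.0 + (np.arange(self.width) + 0.5) * (360.0 / self.width)

    def pixel_latitudes(self) -> np.ndarray:
        """Latitude (deg) of each row's pixel centres, decreasing from +90."""
        return 90.0 - (np.arange(self.height) + 0.5) * (180.0 / self.height)

    def pixel_to_direction(self, row, col) -> np.ndarray:
        """Unit direction(s) of pixel centre(s) in the camera frame."""
        row = np.asarray(row, dtype=int)
        col = np.asarray(col, dtype=int)
        if np.any(row < 0) or np.any(row >= self.height) or np.any(col < 0) or np.any(
            col >= self.width
        ):
            raise IndexError("pixel index out of range")
        lon = -180.0 + (col + 0.5) * (360.0 / self.width)
        lat = 90.0 - (row + 0.5) * (180.0 / self.height)
        return direction_from_lonlat(lon, lat)

    def direction_to_pixel(self, d) -> tuple[np.ndarray, np.ndarray]:
        """Nearest pixel (row, col) containing direction(s) d."""
        d = np.asarray(d, dtype=float)
        lon = np.degrees(np.arctan2(d[..., 0], d[..., 1]))
        lat = np.degrees(np.arctan2(d[..., 2], np.hypot(d[..., 0], d[..., 1])))
        col = np.floor((lon + 180.0) / 360.0 * self.width).astype(int) % self.width
        row = np.floor((90.0 - lat) / 180.0 * self.height).astype(int)
        row = np.clip(row, 0, self.height - 1)
        return row, col

    def directions(self) -> np.ndarray:
        """(H, W, 3) array of all pixel-centre directions (cached)."""
        if "directions" not in self._cache:
            lon = self.pixel_longitudes()
            lat = self.pixel_latitudes()
            self._cache["directions"] = direction_from_lonlat(
                lon[None, :], lat[:, None]
            )
        return self._cache["directions"]

    def solid_angles(self) -> np.ndarray:
        """(H, W) per-pixel solid angles in steradians.

        A(row) = Δλ · (sin φ_top − sin φ_bottom) for the row's latitude band;
        the whole grid sums to 4π.
        """
        if "solid" not in self._cache:
            edges = np.deg2rad(90.0 - np.arange(self.height + 1) * (180.0 / self.height))
            band = np.sin(edges[:-1]) - np.sin(edges[1:])
            dlon = 2.0 * np.pi / self.width
            self._cache["solid"] = np.repeat(
                (dlon * band)[:, None], self.width, axis=1
            )
        return self._cache["solid"]

    def normalized_solid_angles(self) -> np.ndarray:
        """A_i: per-pixel solid angle normalised by the global maximum."""
        A = self.solid_angles()
        return A / A.max()


def orthographic_view(
    raster: np.ndarray,
    grid: CameraGrid,
    hemisphere: str = "forward",
    size: int | None = None,
    fill=np.nan,
) -> np.ndarray:
    """Orthographic projection of one hemisphere onto a disc image.

    Views the visual sphere frontally (forward hemisphere, +y) or from
    behind (backward, −y); the forward direction maps to the disc centre.
    Sampling is nearest-neighbour; pixels outside the disc get ``fill``.
    """
    if hemisphere not in ("forward", "backward"):
        raise ValueError("hemisphere must be 'forward' or 'backward'")
    if size is None:
        size = grid.height
    u = (np.arange(size) + 0.5) / size * 2.0 - 1.0  # x (right) →
    v = 1.0 - (np.arange(size) + 0.5) / size * 2.0  # z (up) ↑
    uu, vv = np.meshgrid(u, v)
    rr2 = uu**2 + vv**2
    inside = rr2 <= 1.0
    yy = np.sqrt(np.clip(1.0 - rr2, 0.0, None))
    if hemisphere == "backward":
        yy = -yy
        uu = -uu  # keep the image non-mirrored when viewed from behind
    d = np.stack([uu, yy, vv], axis=-1)
    out_shape = (size, size) + raster.shape[2:]
    out = np.full(out_shape, fill, dtype=float)
    row, col = grid.direction_to_pixel(d[inside])
    out[inside] = raster[row, col]
    return out
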