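"""Retinal margins and visual-field regions on the viewing sphere.

A bird's eye covers a lobe of the visual sphere bounded above and below by
its retinal margins.  Here each eye's field is described by sampled margin
curves (longitude, upper elevation, lower elevation) in the visual frame,
periodic in longitude; a direction is seen by an eye iff its latitude lies
between the margins at its longitude.  Directions seen by both eyes are
binocular, by one eye monocular (left/right), by neither blind.  The visual
frame is aligned so that the forward direction is the direction of maximum
binocular overlap.

The packaged default table is a *synthetic*, configurable approximation of
a Harris' hawk-like visual field (frontal binocular sector, large lateral
monocular lobes, caudal and dorsal blind sectors); it is not a digitisation
of published figures.  Any user table in the same CSV format
(``eye,longitude_deg,upper_deg,lower_deg``) drops in.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .camera import CameraGrid
from .sphere import wrap_longitude

__all__ = [
    "RegionLabel",
    "RetinalMarginTable",
    "MarginInterpolator",
    "interpolate_margins",
    "classify_directions",
    "max_overlap_direction",
    "region_solid_angle_fractions",
    "build_synthetic_margin_table",
    "load_margin_table",
    "default_margin_table",
]

# Region labels; values are raster codes.
class RegionLabel:
    BLIND = 0
    MONOCULAR_LEFT = 1
    MONOCULAR_RIGHT = 2
    BINOCULAR = 3

    NAMES = {0: "blind", 1: "monocular_left", 2: "monocular_right", 3: "binocular"}


@dataclass
class RetinalMarginTable:
    """Sampled margin curves per eye; longitudes in [-180, 180), degrees.

    Longitudes where ``upper <= lower`` mark arcs the eye does not see.
    With ``symmetric=True`` the left eye is the longitude-mirror of the
    right eye's table.
    """

    eyes: dict  # eye -> DataFrame(longitude_deg, upper_deg, lower_deg)
    symmetric: bool = False
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.symmetric and "right" in self.eyes and "left" not in self.eyes:
            right = self.eyes["right"]
            left = right.copy()
            left["longitude_deg"] = wrap_longitude(-left["longitude_deg"])
            self.eyes["left"] = left.sort_values("longitude_deg").reset_index(drop=True)
        for eye, df in self.eyes.items():
            df = df.sort_values("longitude_deg").reset_index(drop=True)
            if len(df) < 4:
                raise ValueError(f"{eye}: need at least 4 margin samples")
            lons = wrap_longitude(df["longitude_deg"].to_numpy())
            if len(np.unique(lons)) != len(lons):
                raise ValueError(f"{eye}: duplicate longitudes in margin table")
            df["longitude_deg"] = lons
            self.eyes[eye] = df.sort_values("longitude_deg").reset_index(drop=True)


class MarginInterpolator:
    """Periodic piecewise-linear margins: eye, longitude → (upper, lower)."""

    def __init__(self, table: RetinalMarginTable):
        self.table = table
        self._interp = {}
        for eye, df in table.eyes.items():
            lon = df["longitude_deg"].to_numpy()
            up = df["upper_deg"].to_numpy()
            lo = df["lower_deg"].to_numpy()
            # pad one period on each side for seamless wraparound
            lon_p = np.concatenate([lon - 360.0, lon, lon + 360.0])
            self._interp[eye] = (
                lon_p,
                np.concatenate([up, up, up]),
                np.concatenate([lo, lo, lo]),
            )

    @property
    def eye_names(self):
        return list(self._interp)

    def margins(self, eye: str, lon_deg) -> tuple[np.ndarray, np.ndarray]:
        lon = wrap_longitude(lon_deg)
        lon_p, up, lo = self._interp[eye]
        return np.interp(lon, lon_p, up), np.interp(lon, lon_p, lo)

    def sees(self, eye: str, lon_deg, lat_deg) -> np.ndarray:
        up, lo = self.margins(eye, lon_deg)
        lat = np.asarray(lat_deg, dtype=float)
        return (up > lo) & (lat >= lo) & (lat <= up)


def interpolate_margins(table: RetinalMarginTable) -> MarginInterpolator:
    """Build the continuous periodic margin functions from a sampled table."""
    return MarginInterpolator(table)


def classify_directions(grid: CameraGrid, margins: MarginInterpolator) -> np.ndarray:
    """Per-pixel region labels (H, W) over a camera grid.

    Binocular where both eyes see the pixel direction, monocular where
    exactly one does, blind where neither; the labels partition the sphere.
    """
    lon = grid.pixel_longitudes()[None, :]
    lat = grid.pixel_latitudes()[:, None]
    lon2 = np.broadcast_to(lon, grid.shape)
    lat2 = np.broadcast_to(lat, grid.shape)
    left = margins.sees("left", lon2, lat2)
    right = margins.sees("right", lon2, lat2)
    out = np.full(grid.shape, RegionLabel.BLIND, dtype=np.uint8)
    out[left & ~right] = RegionLabel.MONOCULAR_LEFT
    out[right & ~left] = RegionLabel.MONOCULAR_RIGHT
    out[left & right] = RegionLabel.BINOCULAR
    return out


def binocular_extent(margins: MarginInterpolator, lon_deg) -> np.ndarray:
    """Vertical extent (deg) of the binocular overlap at given longitudes."""
    upL, loL = margins.margins("left", lon_deg)
    upR, loR = margins.margins("right", lon_deg)
    seenL = upL > loL
    seenR = upR > loR
    ext = np.minimum(upL, upR) - np.maximum(loL, loR)
    ext = np.where(seenL & seenR, np.maximum(ext, 0.0), 0.0)
    return ext


def max_overlap_direction(
    margins: MarginInterpolator, step_deg: float = 0.1
) -> np.ndarray:
    """Unit direction at the longitude of maximum binocular vertical extent.

    Scans a fine longitude grid; ties break toward longitude 0.  Used to
    re-centre imported margin tables so that forward = maximum overlap.
    """
    lons = np.arange(-180.0, 180.0, step_deg)
    ext = binocular_extent(margins, lons)
    best = ext.max()
    if best <= 0:
        raise ValueError("the eyes' fields do not overlap anywhere")
    cand = lons[ext >= best - 1e-12]
    lon_star = cand[np.argmin(np.abs(cand))]
    from .sphere import direction_from_lonlat

    return direction_from_lonlat(float(lon_star), 0.0)


def region_solid_angle_fractions(grid: CameraGrid, regions: np.ndarray) -> dict:
    """Fraction of the sphere's solid angle per region label."""
    A = grid.solid_angles()
    total = A.sum()
    return {
        name: float(A[regions == code].sum() / total)
        for code, name in RegionLabel.NAMES.items()
    }


def build_synthetic_margin_table(
    eye_center_deg: float = 66.0,
    upper_max_deg: float = 60.0,
    lower_max_deg: float = 70.0,
    field_half_span_deg: float = 84.0,
    shape_half_span_deg: float = 100.0,
    step_deg: float = 6.0,
) -> RetinalMarginTable:
    """Parametric stand-in margin table (synthetic; not digitised data).

    The right eye is centred at ``eye_center_deg`` and spans
    ±``field_half_span_deg`` in longitude; its upper/lower margins follow an
    elliptical profile that pinches closed at the field edge.  Defaults give
    a frontal binocular sector ~36° wide with ~100° vertical extent, a 60°
    caudal blind sector and a dorsal blind cap — the qualitative layout
    reported for Harris' hawks.
    """
    offsets = np.arange(-180.0, 180.0, step_deg)
    rows = []
    for a in offsets:
        if abs(a) < field_half_span_deg:
            s = np.sqrt(max(0.0, 1.0 - (a / shape_half_span_deg) ** 2))
            up, lo = upper_max_deg * s, -lower_max_deg * s
        elif abs(a) == field_half_span_deg:
            up = lo = 0.0
        else:
            up, lo = -1.0, 1.0  # unseen sentinel (upper < lower)
        rows.append((wrap_longitude(eye_center_deg + a), up, lo))
    # ensure the pinch points are in the table even if off the step grid
    for a in (-field_half_span_deg, field_half_span_deg):
        lon = wrap_longitude(eye_center_deg + a)
        if not any(abs(r[0] - lon) < 1e-9 for r in rows):
            rows.append((lon, 0.0, 0.0))
    df = pd.DataFrame(rows, columns=["longitude_deg", "upper_deg", "lower_deg"])
    return RetinalMarginTable(
        eyes={"right": df}, symmetric=True, provenance="synthetic"
    )


def load_margin_table(path, symmetric: bool = False,
                      provenance: str = "user") -> RetinalMarginTable:
    """Read a margin CSV (``eye,longitude_deg,upper_deg,lower_deg``)."""
    df = pd.read_csv(path)
    required = {"eye", "longitude_deg", "upper_deg", "lower_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"margin table must have columns {sorted(required)}")
    eyes = {
        eye: g[["longitude_deg", "upper_deg", "lower_deg"]].reset_index(drop=True)
        for eye, g in df.groupby("eye")
    }
    return RetinalMarginTable(eyes=eyes, symmetric=symmetric, provenance=provenance)


def save_margin_table(table: RetinalMarginTable, path) -> None:
    frames = []
    for eye, df in table.eyes.items():
        d = df.copy()
        d.insert(0, "eye", eye)
        frames.append(d)
    pd.concat(frames).to_csv(path, index=False, float_format="%.6f")


def default_margin_table() -> RetinalMarginTable:
    """The packaged synthetic margin table (see module docstring)."""
    with resources.files("birdgaze.data").joinpath(
        "hawk_margins_synthetic.csv"
    ).open() as fh:
        return load_margin_table(fh, symmetric=False, provenance="synthetic")
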