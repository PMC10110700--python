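"""Gaze statistics computed from per-frame semantic rasters.

The central statistic is the solid-angle-normalised occupancy heatmap

    h_i = n_i / (N · A_i)

where n_i counts the frames in which pixel i saw the label of interest,
N is the number of analysed frames, and A_i is the pixel's solid angle
normalised by the maximum any pixel subtends.  Frames whose head transform
was interpolated are excluded from N, and the analysis is restricted to the
visible regions of the animal's visual field.

Per-frame contours and angular extents of a label, occlusion intervals
against an occluder-free reference render, and fixation-band summaries are
the per-frame counterparts used to describe how the animal holds an object
in its visual field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import CameraGrid
from .rigid_pose import FrameStatus
from .sphere import wrap_longitude

__all__ = [
    "GazeHeatmap",
    "ContourTrack",
    "semantic_heatmap",
    "label_contour",
    "angular_extents",
    "visibility_intervals",
    "fixation_summary",
]


@dataclass
class GazeHeatmap:
    h: np.ndarray          # (H, W) occupancy statistic, 0 outside mask
    n: np.ndarray          # (H, W) per-pixel frame counts
    N: int                 # number of analysed frames
    mask: np.ndarray       # (H, W) pixels included in the analysis


@dataclass
class ContourTrack:
    """Per-frame angular extents of a label (longitude/latitude, degrees)."""

    table: pd.DataFrame  # frame, status, present, lon_min/max/mid, lat_min/max/mid,
    #                      lon_centroid, lat_centroid

    def present_measured(self) -> pd.DataFrame:
        t = self.table
        return t[t["present"] & (t["status"] == FrameStatus.MEASURED.value)]


def _frame_statuses(frame_flags, n: int) -> list[str]:
    out = []
    for f in frame_flags:
        out.append(f.value if isinstance(f, FrameStatus) else str(f))
    if len(out) != n:
        raise ValueError("frame_flags length mismatch with stack")
    return out


def semantic_heatmap(
    stack: np.ndarray,
    label: int,
    grid: CameraGrid,
    region_mask: np.ndarray | None = None,
    frame_flags=None,
    frame_window: np.ndarray | None = None,
) -> GazeHeatmap:
    """Occupancy heatmap h_i = n_i / (N·A_i) of a semantic label.

    Only frames with status ``measured`` (and, if given, inside
    ``frame_window``) contribute; ``region_mask`` restricts the analysis to
    the visible part of the visual field.
    """
    stack = np.asarray(stack)
    F = stack.shape[0]
    if stack.shape[1:] != grid.shape:
        raise ValueError("stack shape does not match the grid")
    include = np.ones(F, dtype=bool)
    if frame_flags is not None:
        statuses = _frame_statuses(frame_flags, F)
        include &= np.array([s == FrameStatus.MEASURED.value for s in statuses])
    if frame_window is not None:
        w = np.zeros(F, dtype=bool)
        w[np.asarray(frame_window, dtype=int)] = True
        include &= w
    N = int(include.sum())
    if N == 0:
        raise ValueError("no frames left after exclusions")
    n = (stack[include] == label).sum(axis=0)
    if region_mask is None:
        region_mask = np.ones(grid.shape, dtype=bool)
    A = grid.normalized_solid_angles()
    h = np.where(region_mask, n / (N * A), 0.0)
    return GazeHeatmap(h=h, n=n, N=N, mask=np.asarray(region_mask, dtype=bool))


def _boundary_mask(raster: np.ndarray, label: int) -> np.ndarray:
    """Label pixels with at least one 4-neighbour outside the label.

    Columns wrap (longitude seam); rows do not — the poles terminate the
    grid, so a label pixel on the top/bottom row is boundary only through
    its in-grid neighbours unless it touches the row edge.
    """
    m = raster == label
    up = np.vstack([np.zeros((1, m.shape[1]), dtype=bool), m[:-1]])
    down = np.vstack([m[1:], np.zeros((1, m.shape[1]), dtype=bool)])
    left = np.roll(m, 1, axis=1)
    right = np.roll(m, -1, axis=1)
    interior = up & down & left & right
    return m & ~interior


def label_contour(
    raster: np.ndarray, label: int, grid: CameraGrid | None = None
) -> list[np.ndarray]:
    """Ordered boundary of a label's region, split at the ±180° seam.

    Returns a list of (k, 2) arrays of (longitude°, latitude°) pixel-centre
    coordinates; each array is an ordered chain of boundary pixels and no
    chain crosses the longitude seam.  Empty list if the label is absent.
    """
    mask = _boundary_mask(raster, label)
    if not mask.any():
        return []
    if grid is None:
        grid = CameraGrid(resolution=raster.shape[1] / 360.0)
    H, W = raster.shape
    lons = grid.pixel_longitudes()
    lats = grid.pixel_latitudes()

    remaining = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}
    chains: list[list[tuple[int, int]]] = []
    while remaining:
        start = min(remaining)
        chain = [start]
        remaining.discard(start)
        while True:
            r, c = chain[-1]
            nxt = None
            for dr in (0, -1, 1):
                for dc in (0, -1, 1):
                    if dr == dc == 0:
                        continue
                    cand = (r + dr, (c + dc) % W)
                    if cand in remaining:
                        nxt = cand
                        break
                if nxt:
                    break
            if nxt is None:
                break
            chain.append(nxt)
            remaining.discard(nxt)
        chains.append(chain)

    out = []
    for chain in chains:
        seg: list[tuple[int, int]] = []
        prev_c = None
        for r, c in chain:
            if prev_c is not None and abs(c - prev_c) > W // 2:  # seam crossing
                out.append(seg)
                seg = []
            seg.append((r, c))
            prev_c = c
        out.append(seg)
    return [
        np.array([[lons[c], lats[r]] for r, c in seg]) for seg in out if seg
    ]


def _circular_interval(lons: np.ndarray) -> tuple[float, float, float]:
    """Minimal arc (mod 360°) containing the given longitudes.

    Returns (lon_min, lon_max, lon_mid); lon_max may exceed 180 when the
    interval crosses the seam, and lon_mid is wrapped into (-180, 180].
    """
    u = np.unique(wrap_longitude(lons))
    if len(u) == 1:
        v = float(u[0])
        return v, v, v
    gaps = np.diff(np.concatenate([u, [u[0] + 360.0]]))
    k = int(np.argmax(gaps))
    lo = u[(k + 1) % len(u)]
    width = 360.0 - gaps[k]
    hi = lo + width
    mid = lo + width / 2.0
    mid = -wrap_longitude(-mid)  # wrap into (-180, 180]
    return float(lo), float(hi), float(mid)


def angular_extents(
    stack: np.ndarray,
    label: int,
    grid: CameraGrid,
    frame_flags=None,
    frame_index: np.ndarray | None = None,
) -> ContourTrack:
    """Per-frame angular interval of a label in longitude and latitude.

    Longitude uses the minimal covering arc mod 360° (seam-safe); latitude
    is a plain min/max.  Interpolated frames are flagged, not dropped, so
    they can be plotted distinctly downstream.  The solid-angle-weighted
    centroid is reported alongside the interval midpoint, since per-frame
    "mean" positions are quoted both ways in the literature.
    """
    stack = np.asarray(stack)
    F = stack.shape[0]
    statuses = (
        _frame_statuses(frame_flags, F)
        if frame_flags is not None
        else [FrameStatus.MEASURED.value] * F
    )
    if frame_index is None:
        frame_index = np.arange(F)
    lons = grid.pixel_longitudes()
    lats = grid.pixel_latitudes()
    A = grid.solid_angles()
    rows = []
    for f in range(F):
        rr, cc = np.nonzero(stack[f] == label)
        if len(rr) == 0:
            rows.append(
                dict(frame=int(frame_index[f]), status=statuses[f], present=False,
                     lon_min=np.nan, lon_max=np.nan, lon_mid=np.nan,
                     lat_min=np.nan, lat_max=np.nan, lat_mid=np.nan,
                     lon_centroid=np.nan, lat_centroid=np.nan)
            )
            continue
        lon_min, lon_max, lon_mid = _circular_interval(lons[cc])
        lat_min, lat_max = float(lats[rr].min()), float(lats[rr].max())
        w = A[rr, cc]
        # centroid via the mean direction vector (seam-safe)
        lon_rad = np.deg2rad(lons[cc])
        mean_sin = (w * np.sin(lon_rad)).sum() / w.sum()
        mean_cos = (w * np.cos(lon_rad)).sum() / w.sum()
        lon_cen = float(np.degrees(np.arctan2(mean_sin, mean_cos)))
        lat_cen = float((w * lats[rr]).sum() / w.sum())
        rows.append(
            dict(frame=int(frame_index[f]), status=statuses[f], present=True,
                 lon_min=lon_min, lon_max=lon_max, lon_mid=lon_mid,
                 lat_min=lat_min, lat_max=lat_max,
                 lat_mid=(lat_min + lat_max) / 2.0,
                 lon_centroid=lon_cen, lat_centroid=lat_cen)
        )
    return ContourTrack(pd.DataFrame(rows))


def visibility_intervals(
    stack: np.ndarray,
    reference_stack: np.ndarray,
    label: int,
    grid: CameraGrid,
    full_tolerance: float = 0.02,
) -> tuple[np.ndarray, dict]:
    """Classify each frame's label visibility against an occlusion-free render.

    ``reference_stack`` must be rendered from the same poses with the
    occluders removed.  Per frame, the solid-angle-weighted label area is
    compared to the reference area: ratio ≥ 1 − ``full_tolerance`` → fully
    visible; 0 < ratio < 1 − tolerance → partially occluded; 0 → not
    visible.  Returns (per-frame state strings, {state: [(start, end)]} with
    inclusive maximal runs in frame positions).
    """
    stack = np.asarray(stack)
    ref = np.asarray(reference_stack)
    if stack.shape != ref.shape:
        raise ValueError("stack and reference shapes differ")
    A = grid.solid_angles()
    states = []
    for f in range(stack.shape[0]):
        area = A[stack[f] == label].sum()
        ref_area = A[ref[f] == label].sum()
        if ref_area == 0:
            states.append("not_visible" if area == 0 else "fully_visible")
        elif area == 0:
            states.append("not_visible")
        elif area / ref_area >= 1.0 - full_tolerance:
            states.append("fully_visible")
        else:
            states.append("partially_occluded")
    states = np.array(states)
    intervals: dict[str, list] = {}
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            intervals.setdefault(str(states[start]), []).append((start, i - 1))
            start = i
    return states, intervals


def fixation_summary(
    track: ContourTrack,
    lon_band: tuple[float, float] = (-10.0, 10.0),
    lat_band: tuple[float, float] = (-10.0, 4.0),
) -> float:
    """Fraction of frames whose full label extent lies inside both bands.

    Only frames where the label is present and the head transform was
    measured are counted.  Bands are closed intervals in degrees.
    """
    if lon_band[0] >= lon_band[1] or lat_band[0] >= lat_band[1]:
        raise ValueError("empty band")
    t = track.present_measured()
    if len(t) == 0:
        return 0.0
    # seam-aware: compare the covering arc's endpoints against the band
    lon_lo = t["lon_min"].to_numpy()
    lon_hi = t["lon_max"].to_numpy()
    # intervals are stored with lon_hi possibly > 180; shift candidates by 360
    inside_lon = np.zeros(len(t), dtype=bool)
    for shift in (-360.0, 0.0, 360.0):
        inside_lon |= (lon_lo + shift >= lon_band[0]) & (lon_hi + shift <= lon_band[1])
    inside_lat = (t["lat_min"] >= lat_band[0]) & (t["lat_max"] <= lat_band[1])
    return float((inside_lon & inside_lat).mean())
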