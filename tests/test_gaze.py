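import numpy as np
import pytest

from birdgaze.camera import CameraGrid
from birdgaze.gaze import (
    angular_extents,
    fixation_summary,
    label_contour,
    semantic_heatmap,
    visibility_intervals,
)
from birdgaze.rigid_pose import FrameStatus
from oracles import counting_heatmap


@pytest.fixture(scope="module")
def small_grid():
    return CameraGrid(resolution=0.25)  # 45 x 90 pixels, fast


def _stack(grid, n_frames):
    return np.zeros((n_frames,) + grid.shape, dtype=int)


def test_heatmap_equation_arithmetic(grid1):
    """h = n/(N·A_i): 1 at an always-occupied equator pixel, 0.5 at half
    occupancy, 1/A_i at a high-latitude pixel."""
    N = 8
    stack = _stack(grid1, N)
    eq_row = 90  # A_i ≈ 1 row (adjacent to the equator)
    stack[:, eq_row, 10] = 5
    stack[: N // 2, eq_row, 20] = 5
    polar_row = 5
    stack[:, polar_row, 30] = 5
    heat = semantic_heatmap(stack, 5, grid1)
    Ai = grid1.normalized_solid_angles()
    np.testing.assert_allclose(heat.h[eq_row, 10], 1.0 / Ai[eq_row, 10])
    np.testing.assert_allclose(heat.h[eq_row, 20], 0.5 / Ai[eq_row, 20])
    np.testing.assert_allclose(heat.h[polar_row, 30], 1.0 / Ai[polar_row, 30])
    assert Ai[eq_row, 10] > 0.999  # equator-adjacent pixel has A_i ≈ 1
    assert heat.h[0, 0] == 0


def test_heatmap_excludes_interpolated_frames(grid1):
    stack = _stack(grid1, 4)
    stack[:, 90, 0] = 1
    flags = [FrameStatus.MEASURED, FrameStatus.INTERPOLATED,
             FrameStatus.MEASURED, FrameStatus.MISSING]
    heat = semantic_heatmap(stack, 1, grid1, frame_flags=flags)
    assert heat.N == 2
    assert heat.n[90, 0] == 2


def test_heatmap_matches_counting_oracle(small_grid, rng):
    stack = rng.integers(0, 3, size=(6,) + small_grid.shape)
    mask = rng.random(small_grid.shape) > 0.3
    include = np.array([True, True, False, True, True, True])
    flags = [FrameStatus.MEASURED if i else FrameStatus.INTERPOLATED
             for i in include]
    heat = semantic_heatmap(stack, 2, small_grid, region_mask=mask,
                            frame_flags=flags)
    h_ref, n_ref = counting_heatmap(stack, 2, small_grid, mask, include)
    np.testing.assert_allclose(heat.h, h_ref, atol=1e-12)
    np.testing.assert_array_equal(heat.n, n_ref)


def test_heatmap_invariant_under_frame_duplication(small_grid, rng):
    stack = rng.integers(0, 2, size=(5,) + small_grid.shape)
    h1 = semantic_heatmap(stack, 1, small_grid).h
    h2 = semantic_heatmap(np.concatenate([stack, stack]), 1, small_grid).h
    np.testing.assert_allclose(h1, h2, atol=1e-12)


def test_heatmap_rejects_empty_frame_set(grid1):
    stack = _stack(grid1, 2)
    with pytest.raises(ValueError):
        semantic_heatmap(stack, 1, grid1,
                         frame_flags=[FrameStatus.INTERPOLATED] * 2)


# ---------------------------------------------------------------------------
# contours

def test_contour_single_pixel_and_block(small_grid):
    raster = np.zeros(small_grid.shape, dtype=int)
    raster[10, 20] = 7
    segs = label_contour(raster, 7, small_grid)
    assert sum(len(s) for s in segs) == 1
    raster2 = np.zeros(small_grid.shape, dtype=int)
    raster2[10:13, 20:23] = 7
    segs2 = label_contour(raster2, 7, small_grid)
    assert sum(len(s) for s in segs2) == 8  # 3x3 block: 8 boundary pixels


def test_contour_matches_boundary_oracle(small_grid, rng):
    """Boundary pixel set equals the brute-force 4-neighbour test on a disc."""
    H, W = small_grid.shape
    raster = np.zeros((H, W), dtype=int)
    rr, cc = np.mgrid[0:H, 0:W]
    disc = (rr - 22) ** 2 + (cc - 40) ** 2 <= 81
    raster[disc] = 3
    segs = label_contour(raster, 3, small_grid)
    got = set()
    lons = small_grid.pixel_longitudes()
    lats = small_grid.pixel_latitudes()
    lut = {(round(lons[c], 6), round(lats[r], 6)): (r, c)
           for r in range(H) for c in range(W)}
    for seg in segs:
        for lon, lat in seg:
            got.add(lut[(round(lon, 6), round(lat, 6))])
    expected = set()
    for r in range(H):
        for c in range(W):
            if raster[r, c] != 3:
                continue
            nb = [raster[r - 1, c] if r > 0 else 0,
                  raster[r + 1, c] if r < H - 1 else 0,
                  raster[r, (c - 1) % W], raster[r, (c + 1) % W]]
            if any(v != 3 for v in nb):
                expected.add((r, c))
    assert got == expected


def test_contour_absent_label_empty(small_grid):
    assert label_contour(np.zeros(small_grid.shape, dtype=int), 9) == []


# ---------------------------------------------------------------------------
# extents

def test_extents_simple_interval(grid1):
    stack = _stack(grid1, 1)
    lons = grid1.pixel_longitudes()
    cols = np.nonzero((lons >= -10) & (lons <= 10))[0]
    stack[0, 90, cols] = 4
    track = angular_extents(stack, 4, grid1)
    row = track.table.iloc[0]
    assert row["present"]
    assert -10.5 <= row["lon_min"] <= -9.5
    assert 9.5 <= row["lon_max"] <= 10.5
    assert abs(row["lon_mid"]) < 0.51
    assert abs(row["lat_mid"] - (-0.5)) < 1e-9


def test_extents_seam_wraparound(grid1):
    """A label spanning 170°..−170° has width 20° and midpoint 180°."""
    stack = _stack(grid1, 1)
    lons = grid1.pixel_longitudes()
    cols = np.nonzero((lons >= 170) | (lons <= -170))[0]
    stack[0, 90, cols] = 4
    row = angular_extents(stack, 4, grid1).table.iloc[0]
    width = row["lon_max"] - row["lon_min"]
    assert abs(width - 20.0) < 1.1
    assert abs(abs(row["lon_mid"]) - 180.0) < 0.51


def test_extents_match_brute_force(small_grid, rng):
    """Random blobs: the covering arc equals an exhaustive scan."""
    for _ in range(5):
        raster = np.zeros(small_grid.shape, dtype=int)
        n_blob = rng.integers(1, 4)
        for _ in range(n_blob):
            r0 = rng.integers(2, small_grid.height - 6)
            c0 = rng.integers(0, small_grid.width)
            raster[r0:r0 + 4, np.arange(c0, c0 + 6) % small_grid.width] = 1
        row = angular_extents(raster[None], 1, small_grid).table.iloc[0]
        lons = np.deg2rad(small_grid.pixel_longitudes())
        occupied = sorted({c for _, c in zip(*np.nonzero(raster == 1))})
        best_width = 361.0
        lons_deg = small_grid.pixel_longitudes()
        vals = np.array(sorted({lons_deg[c] for c in occupied}))
        for i in range(len(vals)):  # try each value as the interval start
            shifted = (vals - vals[i]) % 360.0
            width = shifted.max()
            if width < best_width:
                best_width = width
        np.testing.assert_allclose(row["lon_max"] - row["lon_min"], best_width,
                                   atol=1e-9)


def test_extents_absent_frame_flagged(grid1):
    stack = _stack(grid1, 2)
    stack[0, 90, 180] = 1
    track = angular_extents(stack, 1, grid1)
    assert track.table.iloc[0]["present"]
    assert not track.table.iloc[1]["present"]
    assert np.isnan(track.table.iloc[1]["lon_mid"])


# ---------------------------------------------------------------------------
# visibility + fixation

def test_visibility_interval_classification(grid1):
    F = 10
    stack = _stack(grid1, F)
    ref = _stack(grid1, F)
    ref[:, 88:92, 178:184] = 6  # full reference area every frame
    stack[:] = ref
    stack[3:6, :, :] = 0                      # occluder removes it mid-trial
    stack[6, 88:92, 178:180] = 6
    stack[6, 88:92, 180:184] = 0              # partially occluded
    states, intervals = visibility_intervals(stack, ref, 6, grid1)
    assert list(states[:3]) == ["fully_visible"] * 3
    assert intervals["not_visible"] == [(3, 5)]
    assert intervals["partially_occluded"] == [(6, 6)]
    assert intervals["fully_visible"] == [(0, 2), (7, 9)]


def test_fixation_summary_examples(grid1):
    stack = _stack(grid1, 4)
    stack[:, 90, 180] = 2            # always at the centre
    track = angular_extents(stack, 2, grid1)
    assert fixation_summary(track, (-10, 10), (-10, 4)) == 1.0
    # alternate inside/outside the band
    stack2 = _stack(grid1, 4)
    stack2[0, 90, 180] = 2
    stack2[1, 90, 250] = 2           # ~70° off
    stack2[2, 90, 180] = 2
    stack2[3, 90, 250] = 2
    track2 = angular_extents(stack2, 2, grid1)
    assert fixation_summary(track2, (-10, 10), (-10, 4)) == 0.5
    with pytest.raises(ValueError):
        fixation_summary(track, (10, -10), (-10, 4))
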