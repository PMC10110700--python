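"""Rigid-body pose estimation from motion-capture marker clouds.

The tracked bodies (the head-mounted marker pack and the towed target) are
rigid arrangements of retroreflective markers.  Given a body-fixed template
of marker coordinates, each motion-capture frame yields a least-squares
rigid registration (Kabsch absolute orientation with proper-rotation
correction).  Frames where fewer than three markers were reconstructed are
unrecoverable and marked ``missing``; short gaps can be filled afterwards by
geodesic interpolation of the pose track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .transforms import Transform, slerp_rotation

__all__ = [
    "FrameStatus",
    "MarkerCloudSeries",
    "RigidTemplate",
    "PoseTrack",
    "fit_rigid_template",
    "estimate_pose",
    "build_pose_track",
    "interpolate_poses",
    "head_velocity",
    "UnrecoverableFrameError",
]

# Marker configurations flatter than this along their second principal axis
# are treated as collinear (degenerate for pose estimation).
_COLLINEAR_TOL = 1e-6
# Same-frame ghost markers closer than this are collapsed to their mean.
_DUPLICATE_TOL = 1e-3


class UnrecoverableFrameError(ValueError):
    """Raised when a frame has too few markers for a rigid registration."""


class FrameStatus(Enum):
    MEASURED = "measured"
    INTERPOLATED = "interpolated"
    MISSING = "missing"


@dataclass
class MarkerCloudSeries:
    """Marker positions per frame, in the motion-capture world frame (z-up, m).

    ``positions`` has shape (n_frames, n_markers, 3); ``present`` flags which
    markers were reconstructed in each frame.
    """

    frame_index: np.ndarray
    sample_rate: float
    markers: list[str]
    positions: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        n, m = len(self.frame_index), len(self.markers)
        if self.positions.shape != (n, m, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, {m}, 3)"
            )
        if self.present.shape != (n, m):
            raise ValueError("present shape mismatch")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.positions[self.present])):
            raise ValueError("non-finite position flagged as present")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)


@dataclass
class RigidTemplate:
    """Body-fixed marker coordinates (centroid at the origin), metres."""

    name: str
    markers: list[str]
    local: np.ndarray

    def __post_init__(self) -> None:
        self.local = np.asarray(self.local, dtype=float)
        if len(self.markers) < 3:
            raise ValueError("a rigid template needs at least 3 markers")
        if self.local.shape != (len(self.markers), 3):
            raise ValueError("local coordinates shape mismatch")
        if _second_extent(self.local) <= _COLLINEAR_TOL:
            raise ValueError("marker configuration is collinear")

    @property
    def span(self) -> float:
        """Largest inter-marker distance (m)."""
        d = self.local[:, None, :] - self.local[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).max())


@dataclass
class PoseTrack:
    """Per-frame body→world transform with validity bookkeeping."""

    frame_index: np.ndarray
    sample_rate: float
    poses: list[Transform | None]
    status: list[FrameStatus]

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        n = len(self.frame_index)
        if len(self.poses) != n or len(self.status) != n:
            raise ValueError("poses/status length mismatch")
        for pose, st in zip(self.poses, self.status):
            if st is not FrameStatus.MISSING and pose is None:
                raise ValueError("non-missing frame without a pose")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def translations(self) -> np.ndarray:
        """(n,3) array of translations, NaN where missing."""
        out = np.full((self.n_frames, 3), np.nan)
        for i, (p, st) in enumerate(zip(self.poses, self.status)):
            if st is not FrameStatus.MISSING:
                out[i] = p.translation
        return out

    def valid_mask(self) -> np.ndarray:
        return np.array([s is not FrameStatus.MISSING for s in self.status])

    def measured_mask(self) -> np.ndarray:
        return np.array([s is FrameStatus.MEASURED for s in self.status])


def _second_extent(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return float(s[1]) if len(s) > 1 else 0.0


def _collapse_duplicates(points: np.ndarray, tol: float = _DUPLICATE_TOL) -> np.ndarray:
    """Collapse ghost markers (< tol apart in the same frame) to their mean."""
    pts = points.copy()
    used = np.zeros(len(pts), dtype=bool)
    out = []
    for i in range(len(pts)):
        if used[i]:
            continue
        close = np.linalg.norm(pts - pts[i], axis=1) < tol
        close &= ~used
        out.append(pts[close].mean(axis=0))
        used |= close
    return np.asarray(out)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares proper rotation R, translation t with dst ≈ R src + t.

    Returns (R, t, residual RMS).  Reflection-optimal cases are forced to a
    proper rotation via the determinant sign correction.
    """
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    H = (src - src_c).T @ (dst - dst_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst_c - R @ src_c
    resid = dst - (src @ R.T + t)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return R, t, rms


def _principal_frame(points: np.ndarray) -> np.ndarray:
    """Centroid-origin local coordinates along the principal axes.

    Deterministic, shape-intrinsic sign convention: each principal axis is
    oriented so that the marker projection of largest magnitude along it is
    positive (invariant under rigid motion of the cloud); the third axis is
    flipped if needed to keep the frame right-handed.
    """
    centered = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=True)
    axes = Vt  # rows are principal axes
    for k in range(3):
        proj = centered @ axes[k]
        j = int(np.argmax(np.abs(proj)))
        if proj[j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return centered @ axes.T


def fit_rigid_template(
    series: MarkerCloudSeries, frames=None, name: str = "body"
) -> RigidTemplate:
    """Fit a body-fixed marker template from frames with all markers present.

    The body frame's origin is the marker centroid and its axes are the
    principal axes of the configuration; with several frames the clouds are
    mutually aligned (Kabsch to the first frame's template) and averaged.
    """
    if frames is None:
        frames = np.nonzero(series.present.all(axis=1))[0]
    frames = np.asarray(frames, dtype=int)
    if len(frames) == 0:
        raise ValueError("no frames with all markers present")
    if len(series.markers) < 3:
        raise ValueError("need at least 3 markers")
    for f in frames:
        if not series.present[f].all():
            raise ValueError(f"frame {f} is missing markers")

    clouds = []
    for f in frames:
        pts = series.positions[f]
        if len(_collapse_duplicates(pts)) < 3:
            raise ValueError(f"frame {f}: markers collapse to <3 distinct points")
        clouds.append(pts)
    ref = _principal_frame(clouds[0])
    if _second_extent(ref) <= _COLLINEAR_TOL:
        raise ValueError("marker configuration is collinear")
    acc = np.zeros_like(ref)
    for cloud in clouds:
        centered = cloud - cloud.mean(axis=0)
        R, t, _ = _kabsch(centered, ref)
        acc += centered @ R.T + t
    local = acc / len(clouds)
    local -= local.mean(axis=0)
    return RigidTemplate(name=name, markers=list(series.markers), local=local)


def estimate_pose(
    cloud: np.ndarray,
    template: RigidTemplate,
    present: np.ndarray | None = None,
) -> tuple[Transform, float]:
    """Least-squares rigid registration template→world for one frame.

    Returns the body→world :class:`Transform` and the residual RMS (m).
    Raises :class:`UnrecoverableFrameError` with fewer than three present
    markers or a collinear present subset.
    """
    cloud = np.asarray(cloud, dtype=float)
    if present is None:
        present = np.ones(len(cloud), dtype=bool)
    present = np.asarray(present, dtype=bool)
    if present.sum() < 3:
        raise UnrecoverableFrameError(
            f"only {int(present.sum())} markers present; need >= 3"
        )
    src = template.local[present]
    dst = cloud[present]
    if _second_extent(src) <= _COLLINEAR_TOL:
        raise UnrecoverableFrameError("present marker subset is collinear")
    R, t, rms = _kabsch(src, dst)
    return Transform(R, t, _validated=True), rms


def build_pose_track(series: MarkerCloudSeries, template: RigidTemplate) -> PoseTrack:
    """Per-frame pose estimation; frames with <3 markers are marked missing."""
    if series.n_frames == 0:
        raise ValueError("empty marker series")
    if list(series.markers) != list(template.markers):
        raise ValueError("series and template marker names differ")
    poses: list[Transform | None] = []
    status: list[FrameStatus] = []
    for f in range(series.n_frames):
        try:
            pose, _ = estimate_pose(series.positions[f], template, series.present[f])
            poses.append(pose)
            status.append(FrameStatus.MEASURED)
        except UnrecoverableFrameError:
            poses.append(None)
            status.append(FrameStatus.MISSING)
    return PoseTrack(series.frame_index.copy(), series.sample_rate, poses, status)


def interpolate_poses(track: PoseTrack, max_gap: int = 10) -> PoseTrack:
    """Fill missing-frame gaps of length <= max_gap between measured frames.

    Translation is interpolated linearly; rotation along the geodesic between
    the bounding measured rotations (shortest path).  Filled frames get
    status ``interpolated``; longer gaps stay ``missing``.  Measured frames
    are never altered.
    """
    measured = np.nonzero(track.measured_mask())[0]
    if len(measured) < 2:
        return track
    poses = list(track.poses)
    status = list(track.status)
    for a, b in zip(measured[:-1], measured[1:]):
        gap = b - a - 1
        if gap == 0 or gap > max_gap:
            continue
        if any(status[i] is not FrameStatus.MISSING for i in range(a + 1, b)):
            continue
        pa, pb = track.poses[a], track.poses[b]
        for i in range(a + 1, b):
            alpha = (i - a) / (b - a)
            R = slerp_rotation(pa.rotation, pb.rotation, alpha)
            t = (1 - alpha) * pa.translation + alpha * pb.translation
            poses[i] = Transform(R, t, _validated=True)
            status[i] = FrameStatus.INTERPOLATED
    return PoseTrack(track.frame_index.copy(), track.sample_rate, poses, status)


def head_velocity(track: PoseTrack, smooth_window: int = 5) -> np.ndarray:
    """Per-frame translational velocity (m/s), moving-average smoothed.

    Central differences of translation (one-sided at the ends), then a
    moving average over ``smooth_window`` frames (odd).  Missing frames
    yield NaN and are ignored by the smoother.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    valid = track.valid_mask()
    if valid.sum() < 3:
        raise ValueError("need at least 3 non-missing frames")
    pos = track.translations()
    n = track.n_frames
    dt = 1.0 / track.sample_rate
    vel = np.full((n, 3), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            if not valid[i]:
                continue
            if 0 < i < n - 1 and valid[i - 1] and valid[i + 1]:
                vel[i] = (pos[i + 1] - pos[i - 1]) / (2 * dt)
            elif i + 1 < n and valid[min(i + 1, n - 1)]:
                vel[i] = (pos[i + 1] - pos[i]) / dt
            elif i - 1 >= 0 and valid[i - 1]:
                vel[i] = (pos[i] - pos[i - 1]) / dt
    half = smooth_window // 2
    out = np.full_like(vel, np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = vel[lo:hi]
        good = np.isfinite(window).all(axis=1)
        if good.any():
            out[i] = window[good].mean(axis=0)
    return out
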