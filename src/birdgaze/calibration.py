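"""Calibration of the head-fixed visual coordinate system, and the
counterfactual trajectory coordinate system.

The marker pack sits arbitrarily on the head, so the tracked body frame is
not aligned with the animal's visual field.  The fixed headpack→visual
rotation is estimated from behavioural assumptions during a calibration
window: the bird is assumed to look at a known world point (food in the
falconer's hand, or the perch centre on landing) with its eyes held level.
Each calibration frame then determines a candidate rotation; candidates are
averaged with a chordal mean.

The trajectory coordinate system is a horizon-levelled frame whose forward
(y) axis follows the head's velocity vector, used to render a counterfactual
camera that excludes rotational head movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rigid_pose import FrameStatus, PoseTrack
from .transforms import Transform, chordal_mean_rotation

__all__ = [
    "VisualTransform",
    "DegenerateFrameError",
    "calibrate_point_fixation",
    "visual_track",
    "make_trajectory_frame",
    "trajectory_track",
]

_PARALLEL_TOL = 1e-8


class DegenerateFrameError(ValueError):
    """Velocity too small or too vertical to define a trajectory frame."""


@dataclass(frozen=True)
class VisualTransform:
    """Fixed headpack→visual-frame transform.

    ``rotation`` maps headpack coordinates to visual coordinates (the visual
    frame's forward axis is +y).  ``origin_offset`` is the visual-frame
    origin expressed in the headpack frame (ideally the midpoint between the
    eyes; defaults to the headpack centroid, i.e. zero).
    """

    rotation: np.ndarray
    origin_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(
            self, "origin_offset", np.asarray(self.origin_offset, dtype=float).reshape(3)
        )

    @property
    def gaze_axis_headpack(self) -> np.ndarray:
        """The gaze (visual forward) direction expressed in the headpack frame."""
        return self.rotation.T @ np.array([0.0, 1.0, 0.0])


def _level_axes_from_forward(forward: np.ndarray, world_up: np.ndarray) -> np.ndarray:
    """Visual axes (columns x,y,z) in world coordinates for an eyes-level pose."""
    f = forward / np.linalg.norm(forward)
    right = np.cross(f, world_up)
    nr = np.linalg.norm(right)
    if nr < _PARALLEL_TOL:
        raise DegenerateFrameError("forward direction parallel to world up")
    right /= nr
    up = np.cross(right, f)
    return np.column_stack([right, f, up])


def calibrate_point_fixation(
    track: PoseTrack,
    window,
    target_point,
    world_up=(0.0, 0.0, 1.0),
    origin_offset=(0.0, 0.0, 0.0),
) -> VisualTransform:
    """Estimate the headpack→visual rotation from a point-fixation window.

    For each measured window frame the forward direction is taken as the
    unit vector from the visual-frame origin to ``target_point``; the
    eyes-level assumption fixes the roll about it.  The per-frame candidate
    rotations, pulled back into the headpack frame, are averaged with a
    chordal mean.
    """
    window = np.asarray(window, dtype=int)
    if window.size == 0:
        raise ValueError("empty calibration window")
    target_point = np.asarray(target_point, dtype=float)
    world_up = np.asarray(world_up, dtype=float)
    world_up = world_up / np.linalg.norm(world_up)
    origin_offset = np.asarray(origin_offset, dtype=float)

    candidates = []
    for f in window:
        if track.status[f] is not FrameStatus.MEASURED:
            continue
        pose = track.poses[f]
        origin_world = pose.apply(origin_offset)
        forward = target_point - origin_world
        dist = np.linalg.norm(forward)
        if dist < 1e-9:
            continue
        try:
            visual_axes_world = _level_axes_from_forward(forward, world_up)
        except DegenerateFrameError:
            continue
        # R_H^V = (R_V^W)^T R_H^W
        candidates.append(visual_axes_world.T @ pose.rotation)
    if not candidates:
        raise ValueError("no usable calibration frames in window")
    return VisualTransform(chordal_mean_rotation(candidates), origin_offset)


def visual_track(track: PoseTrack, vt: VisualTransform) -> PoseTrack:
    """Visual-frame pose track (visual→world) from a headpack track."""
    poses: list[Transform | None] = []
    for pose, st in zip(track.poses, track.status):
        if st is FrameStatus.MISSING:
            poses.append(None)
            continue
        R = pose.rotation @ vt.rotation.T
        t = pose.apply(vt.origin_offset)
        poses.append(Transform(R, t, _validated=True))
    return PoseTrack(
        track.frame_index.copy(), track.sample_rate, poses, list(track.status)
    )


def make_trajectory_frame(position, velocity, world_up=(0.0, 0.0, 1.0),
                          min_speed: float = 1e-3) -> Transform:
    """Horizon-levelled frame with y along the velocity: y = v̂,
    x = v̂ × up (horizontal by construction), z = x × y; origin at ``position``."""
    v = np.asarray(velocity, dtype=float)
    up = np.asarray(world_up, dtype=float)
    up = up / np.linalg.norm(up)
    speed = np.linalg.norm(v)
    if speed < min_speed:
        raise DegenerateFrameError(f"speed {speed:.2e} m/s below {min_speed}")
    y = v / speed
    x = np.cross(y, up)
    nx = np.linalg.norm(x)
    if nx < _PARALLEL_TOL:
        raise DegenerateFrameError("velocity parallel to world up")
    x /= nx
    z = np.cross(x, y)
    R = np.column_stack([x, y, z])  # trajectory→world
    return Transform(R, np.asarray(position, dtype=float), _validated=True)


def trajectory_track(
    track: PoseTrack,
    vt: VisualTransform,
    velocities: np.ndarray,
    world_up=(0.0, 0.0, 1.0),
) -> PoseTrack:
    """Per-frame trajectory-frame poses with origin at the visual-frame origin.

    ``velocities`` comes from :func:`birdgaze.rigid_pose.head_velocity` on the
    same track.  Degenerate frames (near-zero or near-vertical velocity) hold
    the previous frame's orientation; leading degenerate frames take the first
    valid one.  Statuses are propagated from the source track.
    """
    velocities = np.asarray(velocities, dtype=float)
    if velocities.shape != (track.n_frames, 3):
        raise ValueError("velocities shape mismatch with track")
    poses: list[Transform | None] = []
    last_R = None
    pending = []  # leading frames awaiting the first valid orientation
    for i, (pose, st) in enumerate(zip(track.poses, track.status)):
        if st is FrameStatus.MISSING:
            poses.append(None)
            continue
        origin = pose.apply(vt.origin_offset)
        try:
            tf = make_trajectory_frame(origin, velocities[i], world_up)
            last_R = tf.rotation
        except DegenerateFrameError:
            if last_R is None:
                poses.append(None)
                pending.append((i, origin))
                continue
            tf = Transform(last_R, origin, _validated=True)
        poses.append(tf)
        for j, orig_j in pending:
            poses[j] = Transform(last_R, orig_j, _validated=True)
        pending.clear()
    if last_R is None:
        raise DegenerateFrameError("no frame with a usable velocity")
    for j, orig_j in pending:
        poses[j] = Transform(last_R, orig_j, _validated=True)
    return PoseTrack(
        track.frame_index.copy(), track.sample_rate, poses, list(track.status)
    )
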