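"""Synthetic motion-capture trials with full ground truth.

No flight recordings are bundled with the package, so every downstream
component is exercised on generated trials that emulate the experimental
setup: a 20 × 6 × 3.3 m flight lab, a rigid 4–5-marker head pack with
sub-millimetre noise and marker dropout, a towed 3-marker target dragged
around pulleys at 5.6 m/s, and scripted gaze behaviours (fixating a point
or a moving object, or looking along the flight path).  The generator
returns the true poses and calibration transform alongside the emitted
marker data, so parameter recovery can be measured exactly.

Trials are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .calibration import VisualTransform
from .rigid_pose import (
    FrameStatus,
    MarkerCloudSeries,
    PoseTrack,
    RigidTemplate,
)
from .scene import (
    Cone,
    Cuboid,
    Cylinder,
    DynamicObject,
    Plane,
    SceneMesh,
    SceneModel,
)
from .transforms import Transform

__all__ = [
    "TrialTruth",
    "make_lab_scene",
    "make_curtain_mesh",
    "simulate_flight",
    "simulate_target",
    "markers_from_pose",
    "make_pursuit_trial",
    "spectral_peak",
    "HEADPACK_TEMPLATE",
    "TARGET_TEMPLATE",
]

LAB_SIZE = (20.0, 6.0, 3.3)         # m
SAMPLE_RATE = 200.0                 # Hz
TARGET_SPEED = 5.6                  # m/s, mean towing speed
TARGET_LENGTH = 0.15                # m
TARGET_DIAMETER = 0.025             # m
PILLAR_HEIGHT = 2.0                 # m
PILLAR_RADIUS = 0.15                # m
PERCH_SEPARATION = 9.0              # m
NOISE_SIGMA = 0.3e-3                # m, isotropic marker noise

# 5-marker head pack, ~6 cm span, non-planar (body frame, metres)
HEADPACK_TEMPLATE = RigidTemplate(
    name="headpack",
    markers=["h1", "h2", "h3", "h4", "h5"],
    local=np.array(
        [
            [0.030, 0.000, 0.000],
            [-0.030, 0.005, 0.000],
            [0.000, 0.025, 0.010],
            [0.010, -0.020, 0.015],
            [-0.012, -0.010, 0.022],
        ]
    )
    - np.array(
        [
            [0.030, 0.000, 0.000],
            [-0.030, 0.005, 0.000],
            [0.000, 0.025, 0.010],
            [0.010, -0.020, 0.015],
            [-0.012, -0.010, 0.022],
        ]
    ).mean(axis=0),
)

# 3-marker target body
_t_local = np.array([[0.000, 0.050, 0.000], [0.012, -0.040, 0.000],
                     [-0.012, -0.010, 0.012]])
TARGET_TEMPLATE = RigidTemplate(
    name="target", markers=["t1", "t2", "t3"], local=_t_local - _t_local.mean(axis=0)
)


def target_primitive() -> Cylinder:
    """The towed target's body-frame cylinder (long axis along body y)."""
    half = TARGET_LENGTH / 2.0
    return Cylinder(
        (0, -half, 0), (0, half, 0), TARGET_DIAMETER / 2.0,
        label="target_body", color=(1.0, 0.55, 0.0),
    )


@dataclass
class TrialTruth:
    """Everything the generator knows about a synthetic trial."""

    head_track: PoseTrack                 # true visual-frame poses (visual→world)
    headpack_track: PoseTrack             # true headpack poses (headpack→world)
    visual_transform: VisualTransform     # true headpack→visual transform
    headpack_markers: MarkerCloudSeries
    target_track: PoseTrack | None
    target_markers: MarkerCloudSeries | None
    scene: SceneModel
    calibration_window: np.ndarray        # frame positions usable for calibration
    calibration_point: np.ndarray         # world point fixated in the window
    flight_window: np.ndarray             # frame positions of the flight proper
    noise_sigma: float
    dropout_p: float
    seed: int
    wingbeat_hz: float = 0.0
    wingbeat_deg: float = 0.0
    bob_amplitude: float = 0.0


# ---------------------------------------------------------------------------
# scene presets

def make_curtain_mesh(
    x: float = 10.0,
    y_range: tuple[float, float] = (1.05, 6.0),
    height: float = 3.3,
    ripple_amplitude: float = 0.05,
    ripple_wavelength: float = 0.8,
    ny: int = 40,
    nz: int = 12,
) -> SceneMesh:
    """Rippled rectangular mesh standing in for the scanned curtain."""
    import trimesh

    ys = np.linspace(y_range[0], y_range[1], ny)
    zs = np.linspace(0.0, height, nz)
    yy, zz = np.meshgrid(ys, zs)
    xx = x + ripple_amplitude * np.sin(2 * np.pi * yy / ripple_wavelength)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for j in range(nz - 1):
        for i in range(ny - 1):
            a = j * ny + i
            faces.append([a, a + 1, a + ny])
            faces.append([a + 1, a + ny + 1, a + ny])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    return SceneMesh(mesh, label="curtain", color=(0.1, 0.1, 0.1))


def _lab_planes() -> list[Plane]:
    lx, ly, lz = LAB_SIZE
    return [
        Plane((0, 0, 0), (0, 0, 1), label="floor", color=(0.45, 0.45, 0.45)),
        Plane((0, 0, lz), (0, 0, -1), label="ceiling", color=(0.8, 0.8, 0.8)),
        Plane((0, 0, 0), (1, 0, 0), label="wall_x_min", color=(0.5, 0.6, 0.5)),
        Plane((lx, 0, 0), (-1, 0, 0), label="wall_x_max", color=(0.5, 0.6, 0.6)),
        Plane((0, 0, 0), (0, 1, 0), label="wall_y_min", color=(0.6, 0.5, 0.5)),
        Plane((0, ly, 0), (0, -1, 0), label="wall_y_max", color=(0.6, 0.6, 0.5)),
    ]


def make_lab_scene(
    preset: str = "box",
    target_track: PoseTrack | None = None,
    curtain_as_mesh: bool = False,
) -> SceneModel:
    """Scene presets for the synthetic lab.

    ``empty``: floor only.  ``box``: the six lab planes.  ``obstacle``: box
    plus four pillars 1.5 m in front of one of two perches set 9 m apart.
    ``pursuit``: box plus a floor-to-ceiling curtain with a ~1.05 m gap,
    pulleys and a start box; pass ``target_track`` to add the towed target
    as a dynamic object.  The curtain defaults to a thin cuboid slab;
    ``curtain_as_mesh`` swaps in the rippled mesh stand-in.
    """
    if preset == "empty":
        prims = [_lab_planes()[0]]
        return SceneModel(primitives=prims)
    if preset not in ("box", "obstacle", "pursuit"):
        raise ValueError(f"unknown preset {preset!r}")
    prims = _lab_planes()
    meshes: list[SceneMesh] = []
    dynamics: list[DynamicObject] = []
    lx, ly, lz = LAB_SIZE
    if preset == "obstacle":
        x_a = (lx - PERCH_SEPARATION) / 2.0       # 5.5
        x_b = x_a + PERCH_SEPARATION              # 14.5
        for name, x in (("perch_a", x_a), ("perch_b", x_b)):
            prims.append(
                Cylinder((x, ly / 2 - 0.5, 1.2), (x, ly / 2 + 0.5, 1.2), 0.025,
                         label=name, color=(0.55, 0.35, 0.2))
            )
        x_p = x_b - 1.5
        for i, y in enumerate(np.linspace(1.2, ly - 1.2, 4)):
            prims.append(
                Cylinder((x_p, y, 0.0), (x_p, y, PILLAR_HEIGHT), PILLAR_RADIUS,
                         label=f"pillar_{i + 1}", color=(0.9, 0.9, 0.85))
            )
    if preset == "pursuit":
        gap = 1.05
        if curtain_as_mesh:
            meshes.append(make_curtain_mesh(x=lx / 2, y_range=(gap, ly)))
        else:
            yc = (gap + ly) / 2.0
            prims.append(
                Cuboid((lx / 2, yc, lz / 2), np.eye(3),
                       (0.02, (ly - gap) / 2.0, lz / 2),
                       label="curtain", color=(0.1, 0.1, 0.1))
            )
        for i, (px, py) in enumerate([(4.0, 1.0), (16.0, 1.0), (16.0, 5.0)]):
            prims.append(
                Cone((px, py, 0.18), (0, 0, -1), 30.0, 0.18,
                     label=f"pulley_{i + 1}", color=(0.3, 0.3, 0.35))
            )
        prims.append(
            Cuboid((2.0, 1.0, 0.15), np.eye(3), (0.2, 0.2, 0.15),
                   label="start_box", color=(0.5, 0.4, 0.3))
        )
        if target_track is not None:
            dynamics.append(
                DynamicObject("target", target_track, target_primitive(),
                              color=(1.0, 0.55, 0.0))
            )
    return SceneModel(primitives=prims, meshes=meshes, dynamics=dynamics)


# ---------------------------------------------------------------------------
# trajectories

def _arclength_spline(waypoints: np.ndarray, n_dense: int = 2000):
    """Natural cubic spline through waypoints, reparametrised by arc length."""
    wp = np.asarray(waypoints, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(wp, axis=0),
                                                            axis=1))])
    if chord[-1] <= 0:
        raise ValueError("zero-length path")
    spline = CubicSpline(chord, wp, axis=0)
    u = np.linspace(0.0, chord[-1], n_dense)
    pts = spline(u)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                        axis=1))])
    return spline, u, s


def _level_orientation(forward: np.ndarray, up=(0, 0, 1)) -> np.ndarray:
    f = forward / np.linalg.norm(forward)
    up = np.asarray(up, dtype=float)
    x = np.cross(f, up)
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("forward direction parallel to up")
    x /= nx
    z = np.cross(x, f)
    return np.column_stack([x, f, z])


def simulate_flight(
    waypoints,
    duration: float,
    gaze: str = "tangent",
    gaze_point=None,
    gaze_track: PoseTrack | None = None,
    wingbeat_deg: float = 0.0,
    wingbeat_hz: float = 0.0,
    bob_amplitude: float = 0.0,
    bob_hz: float | None = None,
    rate: float = SAMPLE_RATE,
    seed: int = 0,
    frame_offset: int = 0,
) -> PoseTrack:
    """Smooth head trajectory with a scripted gaze program.

    The head moves along an arc-length-parametrised spline through the
    waypoints at constant speed.  ``gaze`` is one of:

    - ``"tangent"``: look along the flight path;
    - ``"fixate_point"``: look at ``gaze_point`` (world) every frame;
    - ``"fixate_object"``: look at the origin of ``gaze_track``, matched by
      global frame index.

    Roll is fixed by the eyes-level convention.  ``wingbeat_deg/Hz`` add a
    pitch sinusoid to the orientation; ``bob_amplitude`` (m, at ``bob_hz``,
    default the wingbeat frequency) bobs the head *position* vertically —
    with a fixating gaze this is the configuration in which the wingbeat
    shows up in the trajectory frame but not in the visual frame.

    Returns the true visual-frame pose track (all frames measured).
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    wp = np.asarray(waypoints, dtype=float)
    if len(wp) < 2:
        raise ValueError("need at least 2 waypoints")
    spline, u, s = _arclength_spline(wp)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    s_t = s[-1] * t / duration
    u_t = np.interp(s_t, s, u)
    pos = spline(u_t)
    vel = spline(u_t, 1)  # d(pos)/du; only the direction is used
    if bob_amplitude > 0:
        f_b = bob_hz if bob_hz is not None else wingbeat_hz
        pos = pos.copy()
        pos[:, 2] += bob_amplitude * np.sin(2 * np.pi * f_b * t)

    target_positions = None
    if gaze == "fixate_object":
        if gaze_track is None:
            raise ValueError("fixate_object needs gaze_track")
        lookup = {int(fi): p.translation
                  for fi, p, st in zip(gaze_track.frame_index, gaze_track.poses,
                                       gaze_track.status)
                  if st is not FrameStatus.MISSING}
        target_positions = [lookup.get(frame_offset + i) for i in range(n)]
    elif gaze == "fixate_point":
        if gaze_point is None:
            raise ValueError("fixate_point needs gaze_point")
        gaze_point = np.asarray(gaze_point, dtype=float)
    elif gaze != "tangent":
        raise ValueError(f"unknown gaze program {gaze!r}")

    poses = []
    for i in range(n):
        if gaze == "tangent":
            fwd = vel[i]
        elif gaze == "fixate_point":
            fwd = gaze_point - pos[i]
        else:
            tp = target_positions[i]
            fwd = (tp - pos[i]) if tp is not None else vel[i]
        R = _level_orientation(fwd)
        if wingbeat_deg > 0 and wingbeat_hz > 0:
            pitch = np.deg2rad(wingbeat_deg) * np.sin(2 * np.pi * wingbeat_hz * t[i])
            R = R @ Rotation.from_rotvec([pitch, 0.0, 0.0]).as_matrix()
        poses.append(Transform(R, pos[i], _validated=True))
    return PoseTrack(
        frame_offset + np.arange(n), rate, poses,
        [FrameStatus.MEASURED] * n,
    )


def _fillet_path(points: np.ndarray, radius: float, arc_step: float = 0.02):
    """Dense polyline through ``points`` with circular-arc corner fillets."""
    pts = np.asarray(points, dtype=float)
    dense = [pts[0]]
    for k in range(1, len(pts) - 1):
        a, b, c = pts[k - 1], pts[k], pts[k + 1]
        u1 = (b - a) / np.linalg.norm(b - a)
        u2 = (c - b) / np.linalg.norm(c - b)
        cosang = np.clip(np.dot(u1, u2), -1.0, 1.0)
        turn = np.arccos(cosang)
        if turn < 1e-9:
            dense.append(b)
            continue
        cut = min(radius * np.tan(turn / 2.0),
                  0.49 * np.linalg.norm(b - a), 0.49 * np.linalg.norm(c - b))
        r_eff = cut / np.tan(turn / 2.0)
        p_in = b - cut * u1
        p_out = b + cut * u2
        n_arc = max(2, int(np.ceil(r_eff * turn / arc_step)))
        # arc by spherical interpolation of the tangent directions
        normal = np.cross(u1, u2)
        normal /= np.linalg.norm(normal)
        center = p_in + r_eff * np.cross(normal, u1)
        v0 = p_in - center
        for j in range(1, n_arc + 1):
            ang = turn * j / n_arc
            rot = Rotation.from_rotvec(normal * ang).as_matrix()
            dense.append(center + rot @ v0)
        assert np.allclose(dense[-1], p_out, atol=1e-9)
    dense.append(pts[-1])
    return np.asarray(dense)


def simulate_target(
    pulley_points,
    speed: float = TARGET_SPEED,
    fillet_radius: float = 0.25,
    rate: float = SAMPLE_RATE,
    seed: int = 0,
    frame_offset: int = 0,
) -> PoseTrack:
    """Towed-target track: piecewise-linear circuit with rounded corners.

    The target traverses the pulley circuit at constant mean ``speed`` with
    its long axis tangent to the path.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    pts = np.asarray(pulley_points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 pulley points")
    dense = _fillet_path(pts, fillet_radius)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    duration = total / speed
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    s_t = np.minimum(speed * t, total)
    pos = np.column_stack([np.interp(s_t, s, dense[:, k]) for k in range(3)])
    poses = []
    for i in range(n):
        j = min(np.searchsorted(s, s_t[i], side="right"), len(dense) - 1)
        tangent = dense[j] - dense[j - 1]
        R = _level_orientation(tangent)
        poses.append(Transform(R, pos[i], _validated=True))
    return PoseTrack(
        frame_offset + np.arange(n), rate, poses, [FrameStatus.MEASURED] * n
    )


def markers_from_pose(
    track: PoseTrack,
    template: RigidTemplate,
    sigma: float = NOISE_SIGMA,
    dropout_p: float = 0.0,
    seed: int = 0,
) -> MarkerCloudSeries:
    """Emit a noisy marker cloud series from a true pose track.

    Isotropic Gaussian noise of standard deviation ``sigma`` per coordinate;
    each marker is independently dropped with probability ``dropout_p``.
    """
    if sigma < 0 or not (0 <= dropout_p < 1):
        raise ValueError("invalid noise parameters")
    rng = np.random.default_rng(seed)
    n, m = track.n_frames, len(template.markers)
    positions = np.zeros((n, m, 3))
    present = np.zeros((n, m), dtype=bool)
    for i, (pose, st) in enumerate(zip(track.poses, track.status)):
        noise = rng.normal(scale=sigma, size=(m, 3)) if sigma > 0 else 0.0
        keep = rng.random(m) >= dropout_p
        if st is FrameStatus.MISSING:
            continue
        positions[i] = pose.apply(template.local) + noise
        present[i] = keep
    return MarkerCloudSeries(
        track.frame_index.copy(), track.sample_rate, list(template.markers),
        positions, present,
    )


def spectral_peak(signal: np.ndarray, rate: float,
                  min_hz: float = 0.5) -> tuple[float, float]:
    """(frequency Hz, amplitude) of the dominant spectral component above min_hz.

    Amplitude is the single-sided sine amplitude of the detrended signal.
    """
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    ok = freqs >= min_hz
    k = int(np.argmax(spec[ok]))
    return float(freqs[ok][k]), float(spec[ok][k])


# ---------------------------------------------------------------------------
# full trial assembly

_DEFAULT_HV = Rotation.from_euler("zyx", [25.0, -10.0, 15.0],
                                  degrees=True).as_matrix()


def make_pursuit_trial(
    seed: int = 0,
    duration: float = 2.5,
    rate: float = SAMPLE_RATE,
    calibration_frames: int = 50,
    sigma: float = NOISE_SIGMA,
    dropout_p: float = 0.0,
    wingbeat_hz: float = 4.0,
    bob_amplitude: float = 0.02,
    wingbeat_deg: float = 0.0,
    visual_transform_rotation: np.ndarray | None = None,
    curtain_as_mesh: bool = False,
) -> TrialTruth:
    """A complete synthetic pursuit trial.

    A stationary calibration segment (the bird on the falconer's glove
    looking at a food point) is followed by a ``duration``-second pursuit of
    the towed target through the curtain gap, with the gaze program fixating
    the target and the wingbeat entering as vertical head bobbing.  The
    headpack sits on the head with a fixed, known rotation relative to the
    visual frame; marker data are emitted with noise and dropout.
    """
    rng = np.random.default_rng(seed)
    R_HV = (_DEFAULT_HV if visual_transform_rotation is None
            else np.asarray(visual_transform_rotation, dtype=float))
    vt_true = VisualTransform(R_HV)

    n_cal = calibration_frames
    n_fly = int(round(duration * rate))

    # --- target circuit through the curtain gap (y < 1.05 at x = 10)
    target_track = simulate_target(
        [(3.0, 1.5, 0.25), (9.0, 0.6, 0.25), (11.5, 0.6, 0.25),
         (16.0, 1.4, 0.25), (16.2, 4.6, 0.25)],
        speed=TARGET_SPEED, rate=rate, seed=seed, frame_offset=n_cal,
    )

    # --- calibration segment: stationary head fixating a food point
    cal_pos = np.array([1.0, 3.0, 1.2])
    cal_point = np.array([2.2, 3.0, 1.1])
    cal_poses = []
    for _ in range(n_cal):
        fwd = cal_point - cal_pos
        R = _level_orientation(fwd)
        cal_poses.append(Transform(R, cal_pos, _validated=True))
    cal_track = PoseTrack(np.arange(n_cal), rate, cal_poses,
                          [FrameStatus.MEASURED] * n_cal)

    # --- pursuit flight, gaze fixating the target
    flight_track = simulate_flight(
        [(1.0, 2.8, 1.2), (5.0, 1.8, 1.4), (9.0, 0.6, 1.3),
         (11.5, 0.7, 1.2), (14.5, 1.6, 0.9)],
        duration=duration, gaze="fixate_object", gaze_track=target_track,
        wingbeat_deg=wingbeat_deg, wingbeat_hz=wingbeat_hz,
        bob_amplitude=bob_amplitude, rate=rate, seed=seed, frame_offset=n_cal,
    )

    # --- concatenate calibration + flight into one visual-frame truth track
    head_track = PoseTrack(
        np.arange(n_cal + n_fly), rate,
        list(cal_track.poses) + list(flight_track.poses),
        [FrameStatus.MEASURED] * (n_cal + n_fly),
    )

    # headpack truth: R_H^W = R_V^W · R_H^V, same origin (zero offset)
    hp_poses = [
        Transform(p.rotation @ R_HV, p.translation, _validated=True)
        for p in head_track.poses
    ]
    headpack_track = PoseTrack(
        head_track.frame_index.copy(), rate, hp_poses,
        [FrameStatus.MEASURED] * (n_cal + n_fly),
    )

    hp_markers = markers_from_pose(
        headpack_track, HEADPACK_TEMPLATE, sigma=sigma, dropout_p=dropout_p,
        seed=int(rng.integers(2**31 - 1)),
    )
    tgt_markers = markers_from_pose(
        target_track, TARGET_TEMPLATE, sigma=sigma, dropout_p=0.0,
        seed=int(rng.integers(2**31 - 1)),
    )

    scene = make_lab_scene("pursuit", target_track=target_track,
                           curtain_as_mesh=curtain_as_mesh)
    return TrialTruth(
        head_track=head_track,
        headpack_track=headpack_track,
        visual_transform=vt_true,
        headpack_markers=hp_markers,
        target_track=target_track,
        target_markers=tgt_markers,
        scene=scene,
        calibration_window=np.arange(n_cal),
        calibration_point=cal_point,
        flight_window=np.arange(n_cal, n_cal + n_fly),
        noise_sigma=sigma,
        dropout_p=dropout_p,
        seed=seed,
        wingbeat_hz=wingbeat_hz,
        wingbeat_deg=wingbeat_deg,
        bob_amplitude=bob_amplitude,
    )
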