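import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from birdgaze.rigid_pose import (
    FrameStatus,
    MarkerCloudSeries,
    RigidTemplate,
    UnrecoverableFrameError,
    build_pose_track,
    estimate_pose,
    fit_rigid_template,
    head_velocity,
    interpolate_poses,
)
from birdgaze.synth import HEADPACK_TEMPLATE, markers_from_pose
from birdgaze.transforms import Transform, rotation_angle_deg


def _series_from_clouds(clouds, present=None, rate=200.0, names=None):
    clouds = np.asarray(clouds, dtype=float)
    if present is None:
        present = np.ones(clouds.shape[:2], dtype=bool)
    if names is None:
        names = [f"m{i}" for i in range(clouds.shape[1])]
    return MarkerCloudSeries(np.arange(len(clouds)), rate, names, clouds, present)


# ---------------------------------------------------------------------------
# template fitting

def test_template_single_frame_centroid():
    series = _series_from_clouds([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]])
    tpl = fit_rigid_template(series)
    np.testing.assert_allclose(tpl.local.mean(axis=0), 0, atol=1e-12)
    # centroid-relative distances preserved
    d = np.linalg.norm(tpl.local[0] - tpl.local[1])
    assert abs(d - 1.0) < 1e-12


def test_template_invariant_under_rigid_motion(rng):
    """The same cloud in two poses yields the same body-frame template."""
    base = rng.normal(size=(4, 3)) * 0.05
    T = Transform.random(rng)
    series_a = _series_from_clouds([base])
    series_b = _series_from_clouds([T.apply(base)])
    ta = fit_rigid_template(series_a)
    tb = fit_rigid_template(series_b)
    np.testing.assert_allclose(ta.local, tb.local, atol=1e-9)


def test_template_noisy_recovery():
    """Monte-Carlo: 10 noisy frames recover the generator template to ~3σ/√10."""
    rng = np.random.default_rng(7)
    sigma = 0.5e-3
    truth = HEADPACK_TEMPLATE
    clouds = []
    for _ in range(10):
        T = Transform.random(rng, translation_scale=0.5)
        clouds.append(T.apply(truth.local) + rng.normal(scale=sigma, size=(5, 3)))
    tpl = fit_rigid_template(_series_from_clouds(clouds))
    # align the fitted template to the truth before comparing coordinates
    T_align, rms = estimate_pose(truth.local, tpl)  # fitted template → truth
    aligned = T_align.apply(tpl.local)
    err = np.abs(aligned - truth.local)
    assert err.max() < 3 * sigma  # generous: 3σ single-frame, pooled over 10
    assert rms < 3 * sigma / np.sqrt(10) * 5


def test_template_rejections():
    with pytest.raises(ValueError):
        fit_rigid_template(_series_from_clouds([[[0, 0, 0], [1, 0, 0]]]))
    line = [[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]]
    with pytest.raises(ValueError):
        fit_rigid_template(_series_from_clouds(line))


# ---------------------------------------------------------------------------
# pose estimation

def test_estimate_pose_identity():
    tpl = RigidTemplate("t", ["a", "b", "c"],
                        np.array([[0.05, 0, 0], [-0.05, 0.02, 0], [0, -0.02, 0.03]]))
    T, rms = estimate_pose(tpl.local, tpl)
    assert T.almost_equal(Transform.identity(), tol=1e-12)
    assert rms < 1e-12


def test_estimate_pose_exact_recovery():
    tpl = RigidTemplate("t", ["a", "b", "c"],
                        np.array([[0.05, 0, 0], [-0.05, 0.02, 0], [0, -0.02, 0.03]]))
    truth = Transform.from_rotvec([0, 0, np.pi / 2], [1, 2, 3])
    T, rms = estimate_pose(truth.apply(tpl.local), tpl)
    assert T.almost_equal(truth, tol=1e-9)
    assert rms < 1e-12


def test_estimate_pose_property_random_transforms():
    """Noiseless recovery is exact for 1000 random proper transforms."""
    rng = np.random.default_rng(123)
    tpl = HEADPACK_TEMPLATE
    worst = 0.0
    for _ in range(1000):
        truth = Transform.random(rng, translation_scale=2.0)
        T, _ = estimate_pose(truth.apply(tpl.local), tpl)
        worst = max(worst,
                    np.abs(T.rotation - truth.rotation).max(),
                    np.abs(T.translation - truth.translation).max())
    assert worst < 1e-9


def test_estimate_pose_noisy_matches_simulation_oracle():
    """Median rotation error under σ=0.5 mm noise matches an independent
    Monte-Carlo oracle (scipy align_vectors) run on the same clouds."""
    rng = np.random.default_rng(99)
    tpl = HEADPACK_TEMPLATE
    sigma = 0.5e-3
    errs, oracle_errs = [], []
    for _ in range(300):
        truth = Transform.random(rng, translation_scale=2.0)
        cloud = truth.apply(tpl.local) + rng.normal(scale=sigma, size=(5, 3))
        T, _ = estimate_pose(cloud, tpl)
        errs.append(rotation_angle_deg(T.rotation, truth.rotation))
        rot, _ = Rotation.align_vectors(cloud - cloud.mean(axis=0),
                                        tpl.local - tpl.local.mean(axis=0))
        oracle_errs.append(
            rotation_angle_deg(rot.as_matrix(), truth.rotation)
        )
    # the two routes are the same estimator: distributions agree closely
    assert abs(np.median(errs) - np.median(oracle_errs)) < 0.05
    # sanity: sub-degree accuracy at this noise level and template span
    assert np.median(errs) < 2.0


def test_estimate_pose_residual_invariance(rng):
    """Residual RMS is invariant under a rigid motion of cloud and template."""
    tpl = HEADPACK_TEMPLATE
    cloud = tpl.local + rng.normal(scale=1e-3, size=tpl.local.shape)
    _, rms0 = estimate_pose(cloud, tpl)
    M = Transform.random(rng)
    moved = RigidTemplate("m", tpl.markers, tpl.local)  # template in body frame
    _, rms1 = estimate_pose(M.apply(cloud), moved)
    assert abs(rms0 - rms1) < 1e-9


def test_estimate_pose_too_few_markers():
    tpl = HEADPACK_TEMPLATE
    with pytest.raises(UnrecoverableFrameError):
        estimate_pose(tpl.local, tpl, present=np.array([1, 1, 0, 0, 0], bool))


# ---------------------------------------------------------------------------
# track building / interpolation

def _track_from_truth(n=20, dropout_frame=None, rng_seed=5):
    rng = np.random.default_rng(rng_seed)
    poses = []
    for i in range(n):
        poses.append(Transform.from_rotvec([0, 0, 0.01 * i], [0.02 * i, 0, 1.0]))
    clouds = np.array([p.apply(HEADPACK_TEMPLATE.local) for p in poses])
    present = np.ones((n, 5), dtype=bool)
    if dropout_frame is not None:
        present[dropout_frame, :3] = False  # leaves only 2 markers
    series = _series_from_clouds(clouds, present, names=HEADPACK_TEMPLATE.markers)
    return poses, series


def test_build_pose_track_noiseless_roundtrip():
    poses, series = _track_from_truth()
    track = build_pose_track(series, HEADPACK_TEMPLATE)
    assert all(s is FrameStatus.MEASURED for s in track.status)
    for p, q in zip(track.poses, poses):
        assert p.almost_equal(q, tol=1e-9)


def test_build_pose_track_marks_missing():
    _, series = _track_from_truth(dropout_frame=7)
    track = build_pose_track(series, HEADPACK_TEMPLATE)
    assert track.status[7] is FrameStatus.MISSING
    assert sum(s is FrameStatus.MISSING for s in track.status) == 1


def test_dropout_fraction_matches_generator():
    """Frames with <3 surviving markers are exactly the missing frames."""
    truth_poses, series = _track_from_truth(n=200)
    track_truth = build_pose_track(series, HEADPACK_TEMPLATE)
    noisy = markers_from_pose(track_truth, HEADPACK_TEMPLATE, sigma=0.0,
                              dropout_p=0.4, seed=42)
    track = build_pose_track(noisy, HEADPACK_TEMPLATE)
    expected_missing = (noisy.present.sum(axis=1) < 3)
    got_missing = np.array([s is FrameStatus.MISSING for s in track.status])
    np.testing.assert_array_equal(got_missing, expected_missing)


def test_interpolation_fills_small_gaps_only():
    poses, series = _track_from_truth(n=30)
    track = build_pose_track(series, HEADPACK_TEMPLATE)
    # carve one 1-frame gap and one long gap
    track.poses[5] = None
    track.status[5] = FrameStatus.MISSING
    for i in range(10, 23):
        track.poses[i] = None
        track.status[i] = FrameStatus.MISSING
    out = interpolate_poses(track, max_gap=10)
    assert out.status[5] is FrameStatus.INTERPOLATED
    assert all(out.status[i] is FrameStatus.MISSING for i in range(10, 23))
    # measured frames untouched, count conserved
    assert sum(s is FrameStatus.MEASURED for s in out.status) == sum(
        s is FrameStatus.MEASURED for s in track.status
    )


def test_interpolation_geodesic_midpoint():
    poses = [Transform.identity(), None,
             Transform.from_rotvec([0, 0, np.deg2rad(10)])]
    track_statuses = [FrameStatus.MEASURED, FrameStatus.MISSING,
                      FrameStatus.MEASURED]
    from birdgaze.rigid_pose import PoseTrack

    track = PoseTrack(np.arange(3), 200.0, poses, track_statuses)
    out = interpolate_poses(track, max_gap=1)
    mid = out.poses[1]
    expected = Transform.from_rotvec([0, 0, np.deg2rad(5)])
    assert mid.almost_equal(expected, tol=1e-9)


def test_interpolation_reversal_symmetry():
    """Interpolating the reversed track reverses the interpolated poses."""
    from birdgaze.rigid_pose import PoseTrack

    p0 = Transform.from_rotvec([0.1, -0.2, 0.3], [0, 0, 0])
    p1 = Transform.from_rotvec([0.5, 0.1, -0.4], [1, 2, 3])
    track = PoseTrack(np.arange(4), 200.0, [p0, None, None, p1],
                      [FrameStatus.MEASURED, FrameStatus.MISSING,
                       FrameStatus.MISSING, FrameStatus.MEASURED])
    rev = PoseTrack(np.arange(4), 200.0, [p1, None, None, p0],
                    [FrameStatus.MEASURED, FrameStatus.MISSING,
                     FrameStatus.MISSING, FrameStatus.MEASURED])
    a = interpolate_poses(track, max_gap=5)
    b = interpolate_poses(rev, max_gap=5)
    assert a.poses[1].almost_equal(b.poses[2], tol=1e-9)
    assert a.poses[2].almost_equal(b.poses[1], tol=1e-9)


# ---------------------------------------------------------------------------
# velocity

def _uniform_track(positions, rate=200.0):
    from birdgaze.rigid_pose import PoseTrack

    poses = [Transform(np.eye(3), p) for p in positions]
    return PoseTrack(np.arange(len(positions)), rate, poses,
                     [FrameStatus.MEASURED] * len(positions))


def test_velocity_constant_and_stationary():
    rate = 200.0
    t = np.arange(50) / rate
    pos = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
    v = head_velocity(_uniform_track(pos), smooth_window=5)
    np.testing.assert_allclose(v, np.tile([1.0, 0, 0], (50, 1)), atol=1e-9)
    v0 = head_velocity(_uniform_track(np.zeros((50, 3))), smooth_window=5)
    np.testing.assert_allclose(v0, 0, atol=1e-12)


def test_velocity_sinusoid_gain_closed_form():
    """Peak vertical speed matches 2πfa times the moving-average gain."""
    rate, f, a, w = 200.0, 4.0, 0.05, 5
    t = np.arange(400) / rate
    pos = np.zeros((400, 3))
    pos[:, 2] = a * np.sin(2 * np.pi * f * t)
    v = head_velocity(_uniform_track(pos, rate), smooth_window=w)
    # central difference gain: sin(ωΔt)/Δt; moving-average gain: Dirichlet kernel
    omega = 2 * np.pi * f
    dt = 1 / rate
    gain_diff = np.sin(omega * dt) / (omega * dt)
    gain_ma = np.sin(w * omega * dt / 2) / (w * np.sin(omega * dt / 2))
    expected_peak = omega * a * gain_diff * gain_ma
    peak = np.nanmax(np.abs(v[10:-10, 2]))
    np.testing.assert_allclose(peak, expected_peak, rtol=2e-3)
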