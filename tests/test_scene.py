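import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from birdgaze.scene import (
    Cuboid,
    Cylinder,
    SceneMesh,
    SceneModel,
    clean_mesh,
    deviation_to_markers,
    fit_plane,
    level_mesh_floor,
    primitive_from_markers,
    register_via_plate,
    walls_from_cameras,
)
from birdgaze.transforms import Transform
from oracles import brute_point_mesh_distance


# ---------------------------------------------------------------------------
# plane fitting

def test_fit_plane_exact_floor():
    pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]
    plane, resid = fit_plane(pts)
    np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
    assert resid < 1e-12


def test_fit_plane_alternating_residual():
    # symmetric saddle pattern: the optimal plane is z=0, residual 1 mm
    pts = np.array([[0, 0, 1e-3], [1, 0, -1e-3], [0, 1, -1e-3], [1, 1, 1e-3]])
    _, resid = fit_plane(pts)
    np.testing.assert_allclose(resid, 1e-3, rtol=1e-6)


def test_fit_plane_matches_svd_oracle(rng):
    """Noisy samples of a tilted plane: recovered normal equals direct SVD."""
    normal = np.array([0.1, -0.2, 0.97])
    normal /= np.linalg.norm(normal)
    basis = np.linalg.svd(normal[None])[2][1:]
    uv = rng.uniform(-2, 2, size=(1000, 2))
    pts = uv @ basis + rng.normal(scale=1e-3, size=(1000, 1)) * normal + [0, 0, 1]
    plane, _ = fit_plane(pts)
    centered = pts - pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    oracle = Vt[-1] if Vt[-1][2] > 0 else -Vt[-1]
    np.testing.assert_allclose(plane.normal, oracle, atol=1e-12)
    assert np.degrees(np.arccos(abs(plane.normal @ normal))) < 0.2


def test_fit_plane_rejects_collinear():
    with pytest.raises(ValueError):
        fit_plane([(0, 0, 0), (1, 0, 0), (2, 0, 0)])


# ---------------------------------------------------------------------------
# plate registration

TRIANGLE = np.array([[0.0, 0.0, 0.0], [0.288, 0.0, 0.0], [0.288, 0.288, 0.0]])


def test_plate_identity():
    T, resid = register_via_plate(TRIANGLE, TRIANGLE)
    assert T.almost_equal(Transform.identity(), tol=1e-12)
    assert resid < 1e-12


def test_plate_recovers_given_transform():
    truth = Transform.from_rotvec([0, 0, np.pi / 4], [1.0, -2.0, 0.5])
    T, resid = register_via_plate(TRIANGLE, truth.apply(TRIANGLE))
    assert T.almost_equal(truth, tol=1e-9)
    assert resid < 1e-9


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_plate_exact_for_random_rigid_pairs(seed):
    """register_via_plate is exact for any rigid 3-point pair."""
    rng = np.random.default_rng(seed)
    truth = Transform.random(rng, translation_scale=3.0)
    src = rng.normal(size=(3, 3))
    # re-draw until comfortably non-collinear
    while np.linalg.matrix_rank(src - src.mean(0), tol=1e-3) < 2:
        src = rng.normal(size=(3, 3))
    T, _ = register_via_plate(src, truth.apply(src))
    assert np.abs(T.rotation - truth.rotation).max() < 1e-9
    assert np.abs(T.translation - truth.translation).max() < 1e-9


def test_plate_noisy_falls_back_to_least_squares(rng):
    from birdgaze.rigid_pose import _kabsch

    truth = Transform.from_rotvec([0.3, 0.1, -0.2], [0.5, 0.5, 0.5])
    dst = truth.apply(TRIANGLE) + rng.normal(scale=1e-3, size=(3, 3))
    T, resid = register_via_plate(TRIANGLE, dst)
    R, t, rms = _kabsch(TRIANGLE, dst)
    np.testing.assert_allclose(T.rotation, R, atol=1e-12)
    np.testing.assert_allclose(resid, rms, atol=1e-12)
    assert resid < 5e-3


def test_plate_rejects_collinear():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    with pytest.raises(ValueError):
        register_via_plate(line, line)


# ---------------------------------------------------------------------------
# mesh levelling / deviation

def _flat_square_mesh(z=0.0, n=8, size=4.0):
    xs = np.linspace(0, size, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            faces += [[a, a + 1, a + n], [a + 1, a + n + 1, a + n]]
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def test_level_mesh_already_level():
    sm = SceneMesh(_flat_square_mesh())
    out, tilt, resid = level_mesh_floor(sm, (-0.1, 0.1))
    assert tilt < 1e-9
    assert resid < 1e-12


def test_level_mesh_recovers_2p4_degree_tilt():
    """A mesh tilted 2.4° about x is reported as such and levelled."""
    mesh = _flat_square_mesh()
    tilt = Transform.from_rotvec([np.deg2rad(2.4), 0, 0])
    sm = SceneMesh(mesh, pose=tilt)
    out, tilt_deg, resid = level_mesh_floor(sm, (-1.0, 1.0))
    np.testing.assert_allclose(tilt_deg, 2.4, rtol=1e-9)
    assert resid < 1e-9
    # idempotent: a second application changes nothing
    out2, tilt2, _ = level_mesh_floor(out, (-0.1, 0.1))
    assert tilt2 < 1e-7
    np.testing.assert_allclose(out2.pose.rotation, out.pose.rotation, atol=1e-9)


def test_level_mesh_reduces_floor_residual(rng):
    """Synthetic drifted scan: the post-correction floor residual shrinks."""
    mesh = _flat_square_mesh()
    verts = mesh.vertices.copy()
    verts[:, 2] += rng.normal(scale=2e-3, size=len(verts))
    drifted = trimesh.Trimesh(vertices=verts, faces=mesh.faces, process=False)
    sm = SceneMesh(drifted, pose=Transform.from_rotvec([0.05, -0.03, 0],
                                                       [0, 0, 0.2]))
    pre = np.abs(sm.vertices_world[:, 2]).mean()
    _, _, post = level_mesh_floor(sm, (-1.0, 1.0))
    assert post <= pre


def test_deviation_examples_and_brute_force(rng):
    mesh = _flat_square_mesh()
    sm = SceneMesh(mesh)
    on_surface = np.array([[1.0, 1.0, 0.0], [2.0, 3.0, 0.0]])
    assert deviation_to_markers(sm, on_surface) < 1e-12
    off = np.array([[1.0, 1.0, 0.05]])
    np.testing.assert_allclose(deviation_to_markers(sm, off), 0.05, atol=1e-12)
    pts = rng.uniform([-1, -1, -1], [5, 5, 1], size=(30, 3))
    tri = mesh.vertices[mesh.faces]
    oracle = brute_point_mesh_distance(pts, tri).mean()
    np.testing.assert_allclose(deviation_to_markers(sm, pts), oracle, atol=1e-10)


# ---------------------------------------------------------------------------
# walls, primitives, scene model

def test_walls_from_corner_cameras():
    corners = np.array([[x, y, z] for x in (0, 20) for y in (0, 6)
                        for z in (0.5, 3.3)])
    planes = walls_from_cameras(corners)
    by_label = {p.label: p for p in planes}
    assert by_label["wall_x_min"].point[0] == 0
    assert by_label["wall_x_max"].point[0] == 20
    assert by_label["wall_y_max"].point[1] == 6
    assert by_label["ceiling"].point[2] == pytest.approx(3.3)
    shifted = walls_from_cameras(corners, margin=0.1)
    assert {p.label: p for p in shifted}["wall_x_min"].point[0] == -0.1


def test_walls_contain_jittered_camera_ring(rng):
    ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    cams = np.column_stack([10 + 8 * np.cos(ang), 3 + 2 * np.sin(ang),
                            rng.uniform(2.5, 3.2, 12)])
    cams += rng.normal(scale=0.05, size=cams.shape)
    planes = walls_from_cameras(cams, margin=0.01)
    for p in planes:
        signed = (cams - p.point) @ p.normal
        assert np.all(signed >= -1e-9)  # all cameras inside every plane


def test_pillar_from_top_marker():
    cyl = primitive_from_markers("vertical_cylinder", [(1.0, 2.0, 2.0)],
                                 {"height": 2.0, "radius": 0.15})
    np.testing.assert_allclose(cyl.p0, [1, 2, 0], atol=1e-12)
    np.testing.assert_allclose(cyl.p1, [1, 2, 2], atol=1e-12)
    assert cyl.radius == 0.15


def test_target_body_dimensions():
    from birdgaze.synth import target_primitive

    t = target_primitive()
    assert isinstance(t, Cylinder)
    np.testing.assert_allclose(np.linalg.norm(t.p1 - t.p0), 0.15, atol=1e-12)
    np.testing.assert_allclose(t.radius, 0.0125, atol=1e-12)


def test_cuboid_from_unit_cube_corners():
    cub = primitive_from_markers(
        "cuboid", [(0, 0, 0), (1, 0, 0), (0, 1, 0)], {"height": 1.0}
    )
    assert isinstance(cub, Cuboid)
    np.testing.assert_allclose(cub.center, [0.5, 0.5, 0.5], atol=1e-12)
    np.testing.assert_allclose(cub.half_extents, [0.5, 0.5, 0.5], atol=1e-12)


def test_primitive_insufficient_markers():
    with pytest.raises(ValueError, match="3 markers"):
        primitive_from_markers("cuboid", [(0, 0, 0)], {"height": 1.0})


def test_scene_rejects_duplicate_labels():
    from birdgaze.scene import Plane

    with pytest.raises(ValueError):
        SceneModel(primitives=[Plane((0, 0, 0), (0, 0, 1), label="floor"),
                               Plane((0, 0, 3), (0, 0, -1), label="floor")])


def test_clean_mesh_drops_small_components():
    big = _flat_square_mesh()
    junk = trimesh.Trimesh(
        vertices=np.array([[10, 10, 10], [10.01, 10, 10], [10, 10.01, 10]]),
        faces=np.array([[0, 1, 2]]), process=False,
    )
    merged = trimesh.util.concatenate([big, junk])
    cleaned = clean_mesh(merged, min_component_faces=5)
    assert len(cleaned.faces) == len(big.faces)
    assert cleaned.vertices[:, 0].max() < 10
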