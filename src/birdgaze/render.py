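"""Spherical ray-cast renderer and optic flow on the unit sphere.

Every pixel of the equirectangular camera grid defines a ray from the
camera origin; the nearest intersection across the scene's primitives,
meshes and posed dynamic objects yields per-pixel depth, semantic label,
flat RGB colour and the world hit point.

Optic flow is the angular velocity of scene points across the unit sphere
of viewing directions, reported per pixel in degrees per second.  Two
routes are provided: the instantaneous rigid-scene motion field

    ḋ = −Ω × d + ((v·d) d − v) / r

for camera angular velocity Ω, linear velocity v and range r, and a
finite-difference reprojection of rendered hit points between consecutive
frames (the two agree in the limit of small frame intervals on static
scenes; the reprojection route also covers independently moving objects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .camera import CameraGrid
from .rigid_pose import FrameStatus
from .scene import Cone, Cuboid, Cylinder, Plane, SceneMesh, SceneModel
from .transforms import Transform

__all__ = [
    "RenderFrame",
    "FlowField",
    "intersect",
    "render_frame",
    "analytic_motion_field",
    "reprojection_flow",
]

_EPS = 1e-6  # self-hit guard along the ray (metres)
_MESH_CHUNK = 4_000_000  # max ray×triangle products per vectorised block


@dataclass
class RenderFrame:
    """Per-pixel rasters for one rendered frame."""

    depth: np.ndarray          # (H, W) metres, +inf for no hit
    semantic: np.ndarray       # (H, W) object id, 0 = background
    rgb: np.ndarray            # (H, W, 3) flat per-label colour in [0, 1]
    hit_point: np.ndarray      # (H, W, 3) world coordinates (NaN if no hit)
    camera_pose: Transform     # camera→world pose used


@dataclass
class FlowField:
    """Tangential angular-velocity field on the unit sphere (camera frame)."""

    vectors: np.ndarray     # (H, W, 3) rad/s, orthogonal to the pixel direction
    speed_deg: np.ndarray   # (H, W) angular speed in deg/s


# ---------------------------------------------------------------------------
# ray ↔ primitive intersections (vectorised over rays)

def _intersect_plane(obj: Plane, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    denom = d @ obj.normal
    num = (obj.point - o) @ obj.normal
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    t = np.where((np.abs(denom) > 1e-12) & (t > _EPS), t, np.inf)
    return t


def _disc_hit(o, d, center, normal, radius):
    denom = d @ normal
    num = (center - o) @ normal
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
        ok = (np.abs(denom) > 1e-12) & (t > _EPS)
        t = np.where(ok, t, np.inf)
        p = o + np.where(ok, t, 0.0)[:, None] * d
        ok &= ((p - center) ** 2).sum(axis=1) <= radius**2
    return np.where(ok, t, np.inf)


def _intersect_cylinder(obj: Cylinder, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    axis = obj.p1 - obj.p0
    L = np.linalg.norm(axis)
    a = axis / L
    m = o - obj.p0
    d_par = d @ a
    m_par = m @ a
    d_perp = d - d_par[:, None] * a
    m_perp = m - m_par[:, None] * a
    A = (d_perp**2).sum(axis=1)
    B = 2.0 * (d_perp * m_perp).sum(axis=1)
    C = (m_perp**2).sum(axis=1) - obj.radius**2
    disc = B**2 - 4 * A * C
    best = np.full(len(o), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        for sign in (-1.0, 1.0):
            t = (-B + sign * sq) / (2 * A)
            s = m_par + t * d_par
            ok = np.isfinite(t) & (t > _EPS) & (s >= 0) & (s <= L)
            best = np.where(ok & (t < best), t, best)
    for center in (obj.p0, obj.p1):
        best = np.minimum(best, _disc_hit(o, d, center, a, obj.radius))
    return best


def _intersect_cone(obj: Cone, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    a = obj.axis
    k = np.cos(np.deg2rad(obj.half_angle_deg)) ** 2
    m = o - obj.apex
    d_par = d @ a
    m_par = m @ a
    A = d_par**2 - k * (d * d).sum(axis=1)
    B = 2.0 * (d_par * m_par - k * (d * m).sum(axis=1))
    C = m_par**2 - k * (m * m).sum(axis=1)
    disc = B**2 - 4 * A * C
    best = np.full(len(o), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        for sign in (-1.0, 1.0):
            t = np.where(np.abs(A) > 1e-14, (-B + sign * sq) / (2 * A), np.nan)
            s = m_par + t * d_par
            ok = np.isfinite(t) & (t > _EPS) & (s >= 0) & (s <= obj.height)
            best = np.where(ok & (t < best), t, best)
    base_center = obj.apex + obj.height * a
    base_radius = obj.height * np.tan(np.deg2rad(obj.half_angle_deg))
    return np.minimum(best, _disc_hit(o, d, base_center, a, base_radius))


def _intersect_cuboid(obj: Cuboid, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    ol = (o - obj.center) @ obj.axes
    dl = d @ obj.axes
    he = obj.half_extents
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dl
        t1 = (-he - ol) * inv
        t2 = (he - ol) * inv
    near = np.minimum(t1, t2)
    far = np.maximum(t1, t2)
    # parallel rays miss unless inside the slab
    parallel = np.abs(dl) < 1e-14
    inside_slab = np.abs(ol) <= he
    near = np.where(parallel, np.where(inside_slab, -np.inf, np.inf), near)
    far = np.where(parallel, np.where(inside_slab, np.inf, -np.inf), far)
    tmin = near.max(axis=1)
    tmax = far.min(axis=1)
    hit_entry = (tmax >= tmin) & (tmin > _EPS)
    hit_exit = (tmax >= tmin) & (tmin <= _EPS) & (tmax > _EPS)  # ray starts inside
    t = np.where(hit_entry, tmin, np.where(hit_exit, tmax, np.inf))
    return t


def _intersect_mesh(obj: SceneMesh, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Möller–Trumbore over all triangles, chunked over rays."""
    tri = obj.vertices_world[obj.mesh.faces]  # (T, 3, 3)
    if len(tri) == 0:
        return np.full(len(o), np.inf)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    n_rays = len(o)
    chunk = max(1, _MESH_CHUNK // len(tri))
    best = np.full(n_rays, np.inf)
    for s in range(0, n_rays, chunk):
        os_, ds_ = o[s : s + chunk], d[s : s + chunk]
        pvec = np.cross(ds_[:, None, :], e2[None, :, :])         # (n, T, 3)
        det = (pvec * e1[None, :, :]).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = 1.0 / det
            tvec = os_[:, None, :] - v0[None, :, :]
            u = (tvec * pvec).sum(-1) * inv_det
            qvec = np.cross(tvec, e1[None, :, :])
            v = (qvec * ds_[:, None, :]).sum(-1) * inv_det
            t = (qvec * e2[None, :, :]).sum(-1) * inv_det
        ok = (
            (np.abs(det) > 1e-14)
            & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
            & (t > _EPS)
        )
        t = np.where(ok, t, np.inf)
        best[s : s + chunk] = t.min(axis=1)
    return best


_DISPATCH = {
    Plane: _intersect_plane,
    Cylinder: _intersect_cylinder,
    Cone: _intersect_cone,
    Cuboid: _intersect_cuboid,
    SceneMesh: _intersect_mesh,
}


def intersect(obj, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Nearest hit distances t > ε for rays against one object (+inf = miss)."""
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if o.shape[0] == 1 and d.shape[0] > 1:
        o = np.broadcast_to(o, d.shape)
    fn = _DISPATCH.get(type(obj))
    if fn is None:
        raise TypeError(f"no intersection routine for {type(obj).__name__}")
    return fn(obj, o, d)


# ---------------------------------------------------------------------------
# frame rendering

def _dynamic_pose(dyn, frame: int) -> Transform | None:
    idx = np.nonzero(dyn.track.frame_index == frame)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if dyn.track.status[i] is FrameStatus.MISSING:
        return None
    return dyn.track.poses[i]


def render_frame(
    scene: SceneModel,
    camera_pose: Transform,
    grid: CameraGrid,
    frame: int | None = None,
) -> RenderFrame:
    """Render one frame from a posed spherical camera.

    ``camera_pose`` is the camera→world transform; ``frame`` selects the
    dynamic objects' poses (dynamic objects without a pose at that frame
    are skipped with a warning).  Nearest-hit ties break toward the lowest
    object id.
    """
    H, W = grid.shape
    dirs_cam = grid.directions().reshape(-1, 3)
    dirs_world = dirs_cam @ camera_pose.rotation.T
    origin = camera_pose.translation

    best_t = np.full(H * W, np.inf)
    best_id = np.zeros(H * W, dtype=np.int32)
    objects = list(scene.static_objects)
    n_static = len(objects)
    origins = np.broadcast_to(origin, dirs_world.shape)

    for obj_id, obj in enumerate(objects, start=1):
        t = intersect(obj, origins, dirs_world)
        closer = t < best_t
        best_t = np.where(closer, t, best_t)
        best_id = np.where(closer, obj_id, best_id)

    for k, dyn in enumerate(scene.dynamics):
        obj_id = n_static + 1 + k
        if frame is None:
            pose = None
        else:
            pose = _dynamic_pose(dyn, frame)
        if pose is None:
            warnings.warn(
                f"dynamic object {dyn.label!r} has no pose at frame {frame}; skipped"
            )
            continue
        inv = pose.inverse()
        o_body = inv.apply(origins)
        d_body = inv.apply_vector(dirs_world)
        t = intersect(dyn.primitive, o_body, d_body)
        closer = t < best_t
        best_t = np.where(closer, t, best_t)
        best_id = np.where(closer, obj_id, best_id)

    depth = best_t.reshape(H, W)
    semantic = best_id.reshape(H, W)
    hit = np.isfinite(best_t)
    hit_point = np.full((H * W, 3), np.nan)
    hit_point[hit] = origin + best_t[hit, None] * dirs_world[hit]
    colors = scene.colors()
    lut = np.zeros((max(colors) + 1, 3))
    for i, c in colors.items():
        lut[i] = c
    rgb = lut[best_id].reshape(H, W, 3)
    return RenderFrame(depth, semantic, rgb, hit_point.reshape(H, W, 3), camera_pose)


# ---------------------------------------------------------------------------
# optic flow

def _tangential(flow: np.ndarray, d: np.ndarray) -> np.ndarray:
    return flow - (flow * d).sum(-1, keepdims=True) * d


def analytic_motion_field(
    depth: np.ndarray, grid: CameraGrid, omega, v
) -> FlowField:
    """Instantaneous rigid-scene motion field for a moving camera.

    ``omega`` (rad/s) and ``v`` (m/s) are the camera's angular and linear
    velocity in the *camera* frame; ``depth`` is the per-pixel range.  Where
    depth is infinite the translational term vanishes (background moves only
    under rotation).
    """
    omega = np.asarray(omega, dtype=float)
    v = np.asarray(v, dtype=float)
    d = grid.directions()
    r = np.asarray(depth, dtype=float)
    rot = -np.cross(np.broadcast_to(omega, d.shape), d)
    vd = (d * v).sum(-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        trans = (vd * d - v) / r[..., None]
    trans = np.where(np.isfinite(r)[..., None], trans, 0.0)
    flow = _tangential(rot + trans, d)
    speed = np.linalg.norm(flow, axis=-1)
    return FlowField(flow, np.degrees(speed))


def reprojection_flow(
    frame_k: RenderFrame,
    camera_pose_next: Transform,
    grid: CameraGrid,
    sample_rate: float,
    scene: SceneModel | None = None,
    frame: int | None = None,
    frame_next: int | None = None,
) -> FlowField:
    """Finite-difference flow by advecting hit points from frame k to k+1.

    Each hit point is moved by its object's rigid motion between the two
    frames (identity for static objects and when no scene/frames are given),
    re-expressed in both camera frames, and the great-circle rotation from
    the old to the new direction — scaled by the sample rate and projected
    onto the tangent plane — gives the flow.  Background pixels move under
    camera rotation only.
    """
    H, W = grid.shape
    pose_k = frame_k.camera_pose
    d_cam_k = grid.directions().reshape(-1, 3)
    p = frame_k.hit_point.reshape(-1, 3).copy()
    ids = frame_k.semantic.reshape(-1)
    hit = np.isfinite(frame_k.depth.reshape(-1))

    if scene is not None and frame is not None and frame_next is not None:
        n_static = len(scene.static_objects)
        for k_dyn, dyn in enumerate(scene.dynamics):
            obj_id = n_static + 1 + k_dyn
            sel = hit & (ids == obj_id)
            if not sel.any():
                continue
            pose_a = _dynamic_pose(dyn, frame)
            pose_b = _dynamic_pose(dyn, frame_next)
            if pose_a is None or pose_b is None:
                continue
            motion = pose_b @ pose_a.inverse()
            p[sel] = motion.apply(p[sel])

    inv_next = camera_pose_next.inverse()
    d_next = np.empty_like(d_cam_k)
    # scene points: direction to the (advected) hit point in the next camera
    d_next[hit] = inv_next.apply(p[hit])
    norms = np.linalg.norm(d_next[hit], axis=1, keepdims=True)
    d_next[hit] /= norms
    # background: world direction fixed at infinity, rotation-only
    w = d_cam_k[~hit] @ pose_k.rotation.T
    d_next[~hit] = w @ camera_pose_next.rotation

    cosang = np.clip((d_cam_k * d_next).sum(-1), -1.0, 1.0)
    cross = np.cross(d_cam_k, d_next)
    sinang = np.linalg.norm(cross, axis=-1)
    theta = np.arctan2(sinang, cosang)
    tang = _tangential(d_next, d_cam_k)
    tn = np.linalg.norm(tang, axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(tn > 1e-15, tang / tn, 0.0)
    vectors = (theta[:, None] * sample_rate) * unit
    speed = np.degrees(theta * sample_rate)
    return FlowField(vectors.reshape(H, W, 3), speed.reshape(H, W))
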