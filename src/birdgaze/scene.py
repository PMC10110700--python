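"""Hybrid lab model: labelled geometric primitives plus registered meshes.

The flight arena is modelled the way it was built: floor, ceiling and walls
as planes (walls derived from the motion-capture cameras' positions),
obstacles and perches as cylinders, pulleys as cones, covering boxes as
cuboids, and geometrically complex objects (a floor-to-ceiling curtain) as
triangle meshes registered into the motion-capture frame via a three-marker
fiducial plate.  Dynamic objects (the towed target) carry a primitive in
their body frame and are posed per frame from a pose track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .rigid_pose import PoseTrack, _kabsch, _second_extent
from .transforms import Transform

__all__ = [
    "Plane",
    "Cylinder",
    "Cone",
    "Cuboid",
    "SceneMesh",
    "DynamicObject",
    "SceneModel",
    "fit_plane",
    "register_via_plate",
    "level_mesh_floor",
    "deviation_to_markers",
    "walls_from_cameras",
    "primitive_from_markers",
    "clean_mesh",
]

_DEFAULT_COLOR = (0.6, 0.6, 0.6)


@dataclass
class Plane:
    point: np.ndarray
    normal: np.ndarray
    label: str = "plane"
    color: tuple = _DEFAULT_COLOR

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / nn


@dataclass
class Cylinder:
    """Finite capped cylinder between axis endpoints p0 and p1."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    label: str = "cylinder"
    color: tuple = _DEFAULT_COLOR

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if np.allclose(self.p0, self.p1):
            raise ValueError("cylinder endpoints coincide")


@dataclass
class Cone:
    """Finite cone: apex, unit axis toward the base, half-angle, height (capped)."""

    apex: np.ndarray
    axis: np.ndarray
    half_angle_deg: float
    height: float
    label: str = "cone"
    color: tuple = _DEFAULT_COLOR

    def __post_init__(self):
        self.apex = np.asarray(self.apex, dtype=float)
        a = np.asarray(self.axis, dtype=float)
        self.axis = a / np.linalg.norm(a)
        if not (0 < self.half_angle_deg < 90):
            raise ValueError("half angle must be in (0, 90) degrees")
        if self.height <= 0:
            raise ValueError("cone height must be positive")


@dataclass
class Cuboid:
    """Oriented box: centre, rotation (columns = local axes), half extents."""

    center: np.ndarray
    axes: np.ndarray
    half_extents: np.ndarray
    label: str = "cuboid"
    color: tuple = _DEFAULT_COLOR

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.half_extents = np.asarray(self.half_extents, dtype=float)
        if np.any(self.half_extents <= 0):
            raise ValueError("half extents must be positive")


Primitive = (Plane, Cylinder, Cone, Cuboid)


@dataclass
class SceneMesh:
    """Triangle mesh with a pose into the motion-capture frame."""

    mesh: trimesh.Trimesh
    label: str = "mesh"
    color: tuple = _DEFAULT_COLOR
    pose: Transform = field(default_factory=Transform.identity)

    @property
    def vertices_world(self) -> np.ndarray:
        return self.pose.apply(self.mesh.vertices)

    def posed(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices_world, faces=self.mesh.faces, process=False
        )


@dataclass
class DynamicObject:
    """A primitive in its body frame, posed per frame from a track."""

    label: str
    track: PoseTrack
    primitive: object
    color: tuple = _DEFAULT_COLOR


@dataclass
class SceneModel:
    """Static primitives and meshes plus dynamic objects; labels unique.

    Object ids for rendering are 1-based in insertion order (statics first,
    then dynamics); 0 is background.
    """

    primitives: list = field(default_factory=list)
    meshes: list = field(default_factory=list)
    dynamics: list = field(default_factory=list)

    def __post_init__(self):
        labels = [o.label for o in self.primitives + self.meshes + self.dynamics]
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise ValueError(f"duplicate scene labels: {sorted(dup)}")

    @property
    def static_objects(self) -> list:
        return self.primitives + self.meshes

    def labels(self) -> dict[int, str]:
        """Object id → label (0 reserved for background)."""
        out = {0: "background"}
        for i, obj in enumerate(self.static_objects + self.dynamics, start=1):
            out[i] = obj.label
        return out

    def colors(self) -> dict[int, tuple]:
        out = {0: (0.0, 0.0, 0.0)}
        for i, obj in enumerate(self.static_objects + self.dynamics, start=1):
            out[i] = obj.color
        return out


def fit_plane(points: np.ndarray) -> tuple[Plane, float]:
    """Total-least-squares plane through >= 3 points.

    Normal is the smallest principal direction, oriented toward the +z
    hemisphere; returns (plane, mean absolute signed distance in metres).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if _second_extent(pts) <= 1e-12:
        raise ValueError("points are collinear or coincident")
    _, _, Vt = np.linalg.svd(centered, full_matrices=True)
    normal = Vt[-1]
    if normal[2] < 0 or (normal[2] == 0 and normal[np.argmax(np.abs(normal))] < 0):
        normal = -normal
    residual = float(np.abs(centered @ normal).mean())
    return Plane(centroid, normal, label="fitted_plane"), residual


def _aux_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> Transform:
    """Auxiliary orthonormal frame from an ordered non-collinear triple.

    Origin at p1; x toward p2; z along the triangle normal oriented by the
    vertex order (x × (p3−p1)); y = z × x.  The fixed ordering removes the
    180° ambiguity, so plate corner files must list corners consistently.
    """
    x = p2 - p1
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("plate points 1 and 2 coincide")
    x = x / nx
    z = np.cross(x, p3 - p1)
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("plate points are collinear")
    z = z / nz
    y = np.cross(z, x)
    return Transform(np.column_stack([x, y, z]), p1, _validated=True)


def register_via_plate(
    plate_points_src: np.ndarray,
    plate_points_dst: np.ndarray,
    rigid_tol: float = 1e-6,
) -> tuple[Transform, float]:
    """Transform T_src^dst from the same three physical points seen in two frames.

    Builds the auxiliary frame from the ordered triple in each coordinate
    system and composes dst-frame with the inverse of src-frame; exact for
    rigid pairs.  If the triples are not rigidly related (edge-length
    mismatch beyond ``rigid_tol``), falls back to a 3-point least-squares
    rigid fit.  Returns (transform, residual RMS in the dst frame).
    """
    src = np.asarray(plate_points_src, dtype=float)
    dst = np.asarray(plate_points_dst, dtype=float)
    if src.shape != (3, 3) or dst.shape != (3, 3):
        raise ValueError("expected exactly three 3D points per frame")

    def edges(p):
        return np.array(
            [np.linalg.norm(p[1] - p[0]), np.linalg.norm(p[2] - p[0]),
             np.linalg.norm(p[2] - p[1])]
        )

    if np.abs(edges(src) - edges(dst)).max() <= rigid_tol:
        T = _aux_frame(*dst) @ _aux_frame(*src).inverse()
        resid = float(np.sqrt(((T.apply(src) - dst) ** 2).sum(axis=1).mean()))
        return T, resid
    if _second_extent(src) <= 1e-9 or _second_extent(dst) <= 1e-9:
        raise ValueError("plate points are collinear")
    R, t, rms = _kabsch(src, dst)
    return Transform(R, t, _validated=True), rms


def level_mesh_floor(
    scene_mesh: SceneMesh,
    floor_z_band: tuple[float, float],
    target_plane: Plane | None = None,
) -> tuple[SceneMesh, float, float]:
    """Re-level a scanned mesh so its floor lies on the target plane.

    Vertices (in world pose) whose z falls in ``floor_z_band`` are taken as
    floor samples; a total-least-squares plane is fit to them, and the mesh
    is rotated about the axis normal×target_normal (minimal rotation) and
    translated so the fitted plane lands on the target (default z=0).
    Returns (levelled mesh, pre-correction tilt in degrees, post-correction
    mean floor residual in metres).
    """
    if target_plane is None:
        target_plane = Plane((0, 0, 0), (0, 0, 1), label="floor")
    verts = scene_mesh.vertices_world
    lo, hi = floor_z_band
    sel = (verts[:, 2] >= lo) & (verts[:, 2] <= hi)
    if sel.sum() < 3:
        raise ValueError("floor selector captured fewer than 3 vertices")
    if _second_extent(verts[sel]) <= 1e-9:
        raise ValueError("floor selector vertices are collinear")
    fitted, _ = fit_plane(verts[sel])
    n, m = fitted.normal, target_plane.normal
    cosang = float(np.clip(np.dot(n, m), -1.0, 1.0))
    tilt_deg = float(np.degrees(np.arccos(cosang)))
    axis = np.cross(n, m)
    na = np.linalg.norm(axis)
    if na < 1e-12:
        R = np.eye(3)
    else:
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(axis / na * np.arccos(cosang)).as_matrix()
    # rotate about the fitted-plane centroid, then translate onto the target
    pivot = fitted.point
    rotated_pivot = pivot  # pivot is fixed by the rotation about itself
    gap = float(np.dot(rotated_pivot - target_plane.point, m))
    t = -gap * m
    correction = Transform(R, pivot - R @ pivot + t, _validated=True)
    new_pose = correction @ scene_mesh.pose
    levelled = SceneMesh(scene_mesh.mesh, scene_mesh.label, scene_mesh.color, new_pose)
    new_floor = levelled.vertices_world[sel]
    residual = float(
        np.abs((new_floor - target_plane.point) @ target_plane.normal).mean()
    )
    return levelled, tilt_deg, residual


def deviation_to_markers(scene_mesh: SceneMesh, reference_points: np.ndarray) -> float:
    """Mean unsigned distance (m) from reference points to the mesh surface."""
    pts = np.asarray(reference_points, dtype=float)
    if pts.size == 0 or len(scene_mesh.mesh.faces) == 0:
        raise ValueError("need a non-empty mesh and points")
    posed = scene_mesh.posed()
    _, dist, _ = trimesh.proximity.closest_point_naive(posed, pts.reshape(-1, 3))
    return float(np.mean(dist))


def walls_from_cameras(
    camera_positions: np.ndarray, margin: float = 0.0
) -> list[Plane]:
    """Four wall planes + ceiling from the motion-capture cameras' positions.

    Axis-aligned bounding planes of the camera cloud, each pushed outward by
    ``margin`` metres; the ceiling is the max-z plane.  (The floor plane
    comes from the motion-capture calibration, not from the cameras.)
    """
    pts = np.asarray(camera_positions, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least 4 cameras")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    if np.any(hi[:2] - lo[:2] <= 1e-9):
        raise ValueError("camera positions are degenerate (coplanar)")
    walls = [
        Plane((lo[0] - margin, 0, 0), (1, 0, 0), label="wall_x_min"),
        Plane((hi[0] + margin, 0, 0), (-1, 0, 0), label="wall_x_max"),
        Plane((0, lo[1] - margin, 0), (0, 1, 0), label="wall_y_min"),
        Plane((0, hi[1] + margin, 0), (0, -1, 0), label="wall_y_max"),
        Plane((0, 0, hi[2] + margin), (0, 0, -1), label="ceiling"),
    ]
    return walls


def primitive_from_markers(kind: str, markers: np.ndarray, dimensions: dict,
                           label: str | None = None, color: tuple = _DEFAULT_COLOR):
    """Build a primitive from attached marker positions + measured dimensions.

    Supported constructions:

    - ``vertical_cylinder``: one top-centre marker, dimensions height+radius
      (axis drops straight down from the marker).
    - ``cylinder``: two axis-endpoint markers, dimensions radius.
    - ``cuboid``: three corner markers (origin corner, +x corner, +y corner
      with orthogonal edges), dimensions height (extruded along x̂ × ŷ).
    - ``cone``: apex marker + base-centre marker, dimensions radius.
    """
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    need = {"vertical_cylinder": 1, "cylinder": 2, "cuboid": 3, "cone": 2}
    if kind not in need:
        raise ValueError(f"unknown primitive kind {kind!r}")
    if len(markers) < need[kind]:
        raise ValueError(f"{kind} needs {need[kind]} markers, got {len(markers)}")
    label = label or kind
    if kind == "vertical_cylinder":
        top = markers[0]
        h, r = float(dimensions["height"]), float(dimensions["radius"])
        return Cylinder(top - [0, 0, h], top, r, label=label, color=color)
    if kind == "cylinder":
        r = float(dimensions["radius"])
        return Cylinder(markers[0], markers[1], r, label=label, color=color)
    if kind == "cone":
        apex, base = markers[0], markers[1]
        axis = base - apex
        height = float(np.linalg.norm(axis))
        r = float(dimensions["radius"])
        half_angle = float(np.degrees(np.arctan2(r, height)))
        return Cone(apex, axis / height, half_angle, height, label=label, color=color)
    # cuboid from an origin corner and two adjacent corners
    c0, c1, c2 = markers[:3]
    ex, ey = c1 - c0, c2 - c0
    lx, ly = np.linalg.norm(ex), np.linalg.norm(ey)
    if abs(np.dot(ex, ey)) / (lx * ly) > 1e-6:
        raise ValueError("cuboid corner edges are not orthogonal")
    x, y = ex / lx, ey / ly
    z = np.cross(x, y)
    lz = float(dimensions["height"])
    center = c0 + ex / 2 + ey / 2 + z * lz / 2
    return Cuboid(
        center, np.column_stack([x, y, z]), (lx / 2, ly / 2, lz / 2),
        label=label, color=color,
    )


def clean_mesh(
    mesh: trimesh.Trimesh,
    min_component_faces: int = 10,
    crop_bounds: np.ndarray | None = None,
) -> trimesh.Trimesh:
    """Crop, merge duplicate vertices and drop small isolated pieces.

    Mirrors the usual scanned-mesh clean-up: optional axis-aligned crop,
    duplicate-vertex merge, zero-area triangle removal, and removal of
    connected components with fewer than ``min_component_faces`` faces.
    """
    m = mesh.copy()
    if crop_bounds is not None:
        bounds = np.asarray(crop_bounds, dtype=float)
        inside = np.all(
            (m.vertices >= bounds[0]) & (m.vertices <= bounds[1]), axis=1
        )
        face_ok = inside[m.faces].all(axis=1)
        m.update_faces(face_ok)
        m.remove_unreferenced_vertices()
    m.merge_vertices()
    m.update_faces(m.nondegenerate_faces())
    components = trimesh.graph.connected_components(m.face_adjacency,
                                                    nodes=np.arange(len(m.faces)))
    keep = np.zeros(len(m.faces), dtype=bool)
    for comp in components:
        if len(comp) >= min_component_faces:
            keep[comp] = True
    m.update_faces(keep)
    m.remove_unreferenced_vertices()
    return m
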