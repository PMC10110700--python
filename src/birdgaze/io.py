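"""File formats: marker CSV, pose-track archives, scene YAML.

Marker CSV dialect (shared with the rest of the pipeline)::

    frame,time_s,marker,x,y,z,present

positions in metres, z-up, motion-capture world frame.  Markers missing in
a frame may either be absent rows or carry ``present=0``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .rigid_pose import FrameStatus, MarkerCloudSeries, PoseTrack
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
    "read_marker_csv",
    "write_marker_csv",
    "save_pose_track",
    "load_pose_track",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene_yaml",
    "load_scene_yaml",
]

MARKER_COLUMNS = ["frame", "time_s", "marker", "x", "y", "z", "present"]


def read_marker_csv(path, sample_rate: float | None = None) -> MarkerCloudSeries:
    """Read the marker CSV dialect into a :class:`MarkerCloudSeries`.

    The sample rate is inferred from the ``time_s`` column unless given.
    """
    df = pd.read_csv(path)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    markers = sorted(df["marker"].unique())
    if sample_rate is None:
        t_by_frame = df.groupby("frame")["time_s"].first().sort_index()
        if len(t_by_frame) < 2:
            raise ValueError("cannot infer sample rate from a single frame")
        dts = np.diff(t_by_frame.to_numpy()) / np.diff(t_by_frame.index.to_numpy())
        sample_rate = float(1.0 / np.median(dts))
    fidx = {f: i for i, f in enumerate(frames)}
    midx = {m: j for j, m in enumerate(markers)}
    positions = np.zeros((len(frames), len(markers), 3))
    present = np.zeros((len(frames), len(markers)), dtype=bool)
    rows_present = df["present"].astype(bool).to_numpy()
    fi = df["frame"].map(fidx).to_numpy()
    mj = df["marker"].map(midx).to_numpy()
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    positions[fi, mj] = np.where(np.isfinite(xyz), xyz, 0.0)
    present[fi, mj] = rows_present & np.isfinite(xyz).all(axis=1)
    return MarkerCloudSeries(frames, sample_rate, markers, positions, present)


def write_marker_csv(series: MarkerCloudSeries, path) -> None:
    rows = []
    for i, f in enumerate(series.frame_index):
        t = f / series.sample_rate
        for j, m in enumerate(series.markers):
            p = series.positions[i, j]
            rows.append(
                (int(f), t, m, p[0], p[1], p[2], int(series.present[i, j]))
            )
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def save_pose_track(track: PoseTrack, path) -> None:
    """Pose track as an NPZ archive (rotations, translations, statuses)."""
    n = track.n_frames
    R = np.full((n, 3, 3), np.nan)
    t = np.full((n, 3), np.nan)
    for i, (p, st) in enumerate(zip(track.poses, track.status)):
        if st is not FrameStatus.MISSING:
            R[i] = p.rotation
            t[i] = p.translation
    np.savez(
        path,
        frame_index=track.frame_index,
        sample_rate=np.array(track.sample_rate),
        rotations=R,
        translations=t,
        status=np.array([s.value for s in track.status]),
    )


def load_pose_track(path) -> PoseTrack:
    z = np.load(path, allow_pickle=False)
    statuses = [FrameStatus(s) for s in z["status"]]
    poses = [
        None
        if st is FrameStatus.MISSING
        else Transform(z["rotations"][i], z["translations"][i], _validated=True)
        for i, st in enumerate(statuses)
    ]
    return PoseTrack(z["frame_index"], float(z["sample_rate"]), poses, statuses)


# ---------------------------------------------------------------------------
# scene YAML

def _prim_to_dict(p) -> dict:
    base = {"label": p.label, "color": list(p.color)}
    if isinstance(p, Plane):
        return {"kind": "plane", "point": p.point.tolist(),
                "normal": p.normal.tolist(), **base}
    if isinstance(p, Cylinder):
        return {"kind": "cylinder", "p0": p.p0.tolist(), "p1": p.p1.tolist(),
                "radius": float(p.radius), **base}
    if isinstance(p, Cone):
        return {"kind": "cone", "apex": p.apex.tolist(), "axis": p.axis.tolist(),
                "half_angle_deg": float(p.half_angle_deg),
                "height": float(p.height), **base}
    if isinstance(p, Cuboid):
        return {"kind": "cuboid", "center": p.center.tolist(),
                "axes": p.axes.tolist(),
                "half_extents": p.half_extents.tolist(), **base}
    raise TypeError(f"unknown primitive {type(p).__name__}")


def _prim_from_dict(d: dict):
    kind = d["kind"]
    kwargs = dict(label=d.get("label", kind), color=tuple(d.get("color",
                                                                (0.6, 0.6, 0.6))))
    if kind == "plane":
        return Plane(d["point"], d["normal"], **kwargs)
    if kind == "cylinder":
        return Cylinder(d["p0"], d["p1"], d["radius"], **kwargs)
    if kind == "cone":
        return Cone(d["apex"], d["axis"], d["half_angle_deg"], d["height"], **kwargs)
    if kind == "cuboid":
        return Cuboid(d["center"], d["axes"], d["half_extents"], **kwargs)
    raise ValueError(f"unknown primitive kind {kind!r}")


def scene_to_dict(scene: SceneModel, mesh_dir: Path | None = None) -> dict:
    """Serialisable scene description; meshes are written as OBJ next to it."""
    out = {"primitives": [_prim_to_dict(p) for p in scene.primitives],
           "meshes": [], "dynamics": []}
    for sm in scene.meshes:
        entry = {"label": sm.label, "color": list(sm.color)}
        if mesh_dir is not None:
            mesh_dir = Path(mesh_dir)
            mesh_dir.mkdir(parents=True, exist_ok=True)
            mesh_path = mesh_dir / f"{sm.label}.obj"
            sm.posed().export(mesh_path)
            entry["file"] = mesh_path.name
        out["meshes"].append(entry)
    for dyn in scene.dynamics:
        out["dynamics"].append(
            {"label": dyn.label, "color": list(dyn.color),
             "primitive": _prim_to_dict(dyn.primitive)}
        )
    return out


def scene_from_dict(d: dict, mesh_dir: Path | None = None,
                    dynamic_tracks: dict | None = None) -> SceneModel:
    """Rebuild a scene; dynamic tracks are supplied by label."""
    prims = [_prim_from_dict(p) for p in d.get("primitives", [])]
    meshes = []
    for entry in d.get("meshes", []):
        if "file" not in entry:
            continue
        mesh = trimesh.load(Path(mesh_dir or ".") / entry["file"], process=False)
        meshes.append(
            SceneMesh(mesh, label=entry["label"], color=tuple(entry["color"]))
        )
    dynamics = []
    for entry in d.get("dynamics", []):
        track = (dynamic_tracks or {}).get(entry["label"])
        if track is None:
            raise ValueError(f"no pose track supplied for dynamic object "
                             f"{entry['label']!r}")
        dynamics.append(
            DynamicObject(entry["label"], track, _prim_from_dict(entry["primitive"]),
                          color=tuple(entry["color"]))
        )
    return SceneModel(primitives=prims, meshes=meshes, dynamics=dynamics)


def save_scene_yaml(scene: SceneModel, path) -> None:
    path = Path(path)
    doc = scene_to_dict(scene, mesh_dir=path.parent)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))


def load_scene_yaml(path, dynamic_tracks: dict | None = None) -> SceneModel:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    return scene_from_dict(doc, mesh_dir=path.parent, dynamic_tracks=dynamic_tracks)


def write_preview_png(raster: np.ndarray, path, vmax: float | None = None) -> None:
    """16-bit grayscale PNG preview of a scalar raster (depth, speed, h...).

    Infinities are mapped to the maximum; ``vmax`` caps the display range.
    """
    import imageio.v3 as iio

    x = np.asarray(raster, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("raster has no finite values")
    hi = vmax if vmax is not None else x[finite].max()
    lo = x[finite].min()
    span = hi - lo if hi > lo else 1.0
    scaled = np.clip((np.where(finite, x, hi) - lo) / span, 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())
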