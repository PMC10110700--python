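"""End-to-end trial pipeline: calibrate → build-scene → render → flow → analyze.

Each stage reads the trial configuration and earlier stages' artifacts from
a run directory, writes its own outputs there, and records a manifest with
input hashes so unchanged stages are skipped on re-runs.  Outputs contain
no timestamps: identical config + seed reproduces byte-identical rasters
and tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .calibration import (
    calibrate_point_fixation,
    trajectory_track,
    visual_track,
)
from .camera import CameraGrid
from .gaze import angular_extents, fixation_summary, semantic_heatmap
from .render import render_frame, reprojection_flow
from .rigid_pose import (
    build_pose_track,
    fit_rigid_template,
    head_velocity,
    interpolate_poses,
)
from .visual_field import (
    RegionLabel,
    classify_directions,
    default_margin_table,
    interpolate_margins,
    load_margin_table,
)

log = logging.getLogger("birdgaze")

STAGES = ["calibrate", "build-scene", "render", "flow", "analyze"]
_DEPS = {
    "calibrate": [],
    "build-scene": [],
    "render": ["calibrate", "build-scene"],
    "flow": ["render"],
    "analyze": ["render"],
}

__all__ = ["TrialConfig", "run_pipeline", "PipelineError", "STAGES"]


class PipelineError(RuntimeError):
    pass


@dataclass
class TrialConfig:
    """Everything a trial run needs; round-trips losslessly through YAML."""

    out_dir: str
    markers: str                      # headpack marker CSV
    scene: str                        # scene YAML
    target_markers: str | None = None
    margins: str | None = None        # margin CSV (packaged default if None)
    calibration_target: list = field(default_factory=lambda: [0.0, 0.0, 0.0])
    calibration_window: list = field(default_factory=lambda: [0, 50])
    world_up: list = field(default_factory=lambda: [0.0, 0.0, 1.0])
    origin_offset: list = field(default_factory=lambda: [0.0, 0.0, 0.0])
    resolution: float = 5.0
    camera_tracks: list = field(default_factory=lambda: ["visual"])
    frames: list | None = None        # [start, stop) frame-position window
    target_label: str = "target"
    max_gap: int = 10
    smooth_window: int = 5
    seed: int = 0

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path) -> "TrialConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def resolve(self, key: str) -> Path:
        return Path(getattr(self, key))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_signature(config: TrialConfig, stage: str, inputs: list[Path]) -> str:
    payload = {
        "config": asdict(config),
        "stage": stage,
        "inputs": {str(p): _hash_file(p) for p in sorted(inputs) if p.exists()},
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _manifest_path(out: Path, stage: str) -> Path:
    return out / f"manifest_{stage}.json"


def _up_to_date(out: Path, stage: str, signature: str) -> bool:
    mp = _manifest_path(out, stage)
    if not mp.exists():
        return False
    doc = json.loads(mp.read_text())
    if doc.get("signature") != signature:
        return False
    return all((out / f).exists() for f in doc.get("outputs", []))


def _write_manifest(out: Path, stage: str, signature: str, outputs: list[str]) -> None:
    _manifest_path(out, stage).write_text(
        json.dumps({"stage": stage, "signature": signature, "outputs": outputs},
                   indent=2, sort_keys=True)
    )


def _frame_positions(config: TrialConfig, track) -> np.ndarray:
    if config.frames is None:
        return np.arange(track.n_frames)
    a, b = config.frames
    return np.arange(a, min(b, track.n_frames))


def _load_headpack_track(out: Path):
    return bio.load_pose_track(out / "headpack_track.npz")


def _stage_calibrate(config: TrialConfig, out: Path) -> list[str]:
    series = bio.read_marker_csv(config.resolve("markers"))
    template = fit_rigid_template(series, name="headpack")
    track = build_pose_track(series, template)
    track = interpolate_poses(track, max_gap=config.max_gap)
    vt = calibrate_point_fixation(
        track,
        np.arange(*config.calibration_window),
        np.asarray(config.calibration_target, dtype=float),
        world_up=np.asarray(config.world_up, dtype=float),
        origin_offset=np.asarray(config.origin_offset, dtype=float),
    )
    bio.save_pose_track(track, out / "headpack_track.npz")
    bio.save_json(
        {"rotation": vt.rotation.tolist(),
         "origin_offset": vt.origin_offset.tolist()},
        out / "calibration.json",
    )
    return ["headpack_track.npz", "calibration.json"]


def _stage_build_scene(config: TrialConfig, out: Path) -> list[str]:
    dynamic_tracks = {}
    if config.target_markers is not None:
        tseries = bio.read_marker_csv(config.resolve("target_markers"))
        ttemplate = fit_rigid_template(tseries, name="target")
        ttrack = interpolate_poses(build_pose_track(tseries, ttemplate),
                                   max_gap=config.max_gap)
        bio.save_pose_track(ttrack, out / "target_track.npz")
        dynamic_tracks[config.target_label] = ttrack
    # validate the scene document end-to-end
    bio.load_scene_yaml(config.resolve("scene"), dynamic_tracks=dynamic_tracks)
    return ["target_track.npz"] if dynamic_tracks else []


def _load_scene(config: TrialConfig, out: Path):
    dynamic_tracks = {}
    if (out / "target_track.npz").exists():
        dynamic_tracks[config.target_label] = bio.load_pose_track(
            out / "target_track.npz"
        )
    return bio.load_scene_yaml(config.resolve("scene"),
                               dynamic_tracks=dynamic_tracks)


def _camera_tracks(config: TrialConfig, out: Path):
    from .calibration import VisualTransform

    cal = bio.load_json(out / "calibration.json")
    vt = VisualTransform(np.asarray(cal["rotation"]),
                         np.asarray(cal["origin_offset"]))
    hp = _load_headpack_track(out)
    tracks = {}
    if "visual" in config.camera_tracks:
        tracks["visual"] = visual_track(hp, vt)
    if "trajectory" in config.camera_tracks:
        vel = head_velocity(hp, smooth_window=config.smooth_window)
        tracks["trajectory"] = trajectory_track(
            hp, vt, vel, world_up=np.asarray(config.world_up, dtype=float)
        )
    return tracks


def _stage_render(config: TrialConfig, out: Path) -> list[str]:
    scene = _load_scene(config, out)
    grid = CameraGrid(resolution=config.resolution)
    outputs = []
    for name, cam_track in _camera_tracks(config, out).items():
        positions = _frame_positions(config, cam_track)
        H, W = grid.shape
        sem = np.zeros((len(positions), H, W), dtype=np.uint16)
        depth = np.full((len(positions), H, W), np.inf, dtype=np.float32)
        rot = np.full((len(positions), 3, 3), np.nan)
        trans = np.full((len(positions), 3), np.nan)
        statuses = []
        for k, pos in enumerate(positions):
            st = cam_track.status[pos]
            statuses.append(st.value)
            if cam_track.poses[pos] is None:
                continue
            pose = cam_track.poses[pos]
            frame_no = int(cam_track.frame_index[pos])
            rf = render_frame(scene, pose, grid, frame=frame_no)
            sem[k] = rf.semantic
            depth[k] = rf.depth
            rot[k] = pose.rotation
            trans[k] = pose.translation
        fname = f"render_{name}.npz"
        np.savez(
            out / fname,
            semantic=sem,
            depth=depth,
            frame_index=cam_track.frame_index[positions],
            status=np.array(statuses),
            rotations=rot,
            translations=trans,
            resolution=np.array(grid.resolution),
            labels=json.dumps(scene.labels()),
        )
        outputs.append(fname)
    return outputs


def _stage_flow(config: TrialConfig, out: Path) -> list[str]:
    scene = _load_scene(config, out)
    grid = CameraGrid(resolution=config.resolution)
    outputs = []
    for name, cam_track in _camera_tracks(config, out).items():
        positions = _frame_positions(config, cam_track)
        z = np.load(out / f"render_{name}.npz", allow_pickle=False)
        H, W = grid.shape
        speed = np.full((len(positions), H, W), np.nan, dtype=np.float32)
        for k in range(len(positions) - 1):
            p0, p1 = positions[k], positions[k + 1]
            if cam_track.poses[p0] is None or cam_track.poses[p1] is None:
                continue
            from .render import RenderFrame

            rf = RenderFrame(
                depth=z["depth"][k].astype(float),
                semantic=z["semantic"][k].astype(np.int32),
                rgb=np.zeros((H, W, 3)),
                hit_point=_hit_points(z, k, grid),
                camera_pose=cam_track.poses[p0],
            )
            ff = reprojection_flow(
                rf, cam_track.poses[p1], grid, cam_track.sample_rate,
                scene=scene,
                frame=int(cam_track.frame_index[p0]),
                frame_next=int(cam_track.frame_index[p1]),
            )
            speed[k] = ff.speed_deg
        fname = f"flow_{name}.npz"
        np.savez(out / fname, speed_deg=speed,
                 frame_index=cam_track.frame_index[positions])
        outputs.append(fname)
    return outputs


def _hit_points(z, k: int, grid: CameraGrid) -> np.ndarray:
    depth = z["depth"][k].astype(float)
    R = z["rotations"][k]
    t = z["translations"][k]
    d_world = grid.directions() @ R.T
    hp = t + depth[..., None] * d_world
    hp[~np.isfinite(depth)] = np.nan
    return hp


def _stage_analyze(config: TrialConfig, out: Path) -> list[str]:
    grid = CameraGrid(resolution=config.resolution)
    if config.margins is not None:
        table = load_margin_table(config.resolve("margins"), symmetric=False)
    else:
        table = default_margin_table()
    margins = interpolate_margins(table)
    regions = classify_directions(grid, margins)
    visible = regions != RegionLabel.BLIND
    outputs = []
    for name in config.camera_tracks:
        z = np.load(out / f"render_{name}.npz", allow_pickle=False)
        labels = {v: int(k) for k, v in json.loads(str(z["labels"])).items()}
        if config.target_label not in labels:
            raise PipelineError(
                f"label {config.target_label!r} not in the rendered scene"
            )
        label_id = labels[config.target_label]
        stack = z["semantic"]
        flags = list(z["status"])
        # In the trajectory frame the visual-field margins are not meaningful;
        # restrict to the visible region only for the visual camera.
        mask = visible if name == "visual" else None
        heat = semantic_heatmap(stack, label_id, grid, region_mask=mask,
                                frame_flags=flags)
        track = angular_extents(stack, label_id, grid, frame_flags=flags,
                                frame_index=z["frame_index"])
        frac = fixation_summary(track)
        hname, cname, sname = (
            f"heatmap_{name}.npz", f"extents_{name}.csv", f"summary_{name}.json"
        )
        np.savez(out / hname, h=heat.h, n=heat.n, N=np.array(heat.N),
                 mask=heat.mask)
        track.table.to_csv(out / cname, index=False, float_format="%.6f")
        bio.save_json(
            {"fixation_fraction": frac, "analysed_frames": heat.N,
             "camera_track": name},
            out / sname,
        )
        outputs += [hname, cname, sname]
    return outputs


_STAGE_FUNCS = {
    "calibrate": _stage_calibrate,
    "build-scene": _stage_build_scene,
    "render": _stage_render,
    "flow": _stage_flow,
    "analyze": _stage_analyze,
}


def run_pipeline(config: TrialConfig, stages=None, force: bool = False) -> dict:
    """Run the requested stages; returns {stage: {status, outputs}}.

    Stage dependencies are enforced: a stage whose prerequisites have not
    produced their manifests raises :class:`PipelineError` naming the
    missing stage.  Completed, up-to-date stages are skipped unless
    ``force``.
    """
    if stages is None:
        stages = list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {}
    for stage in stages:
        for dep in _DEPS[stage]:
            if dep not in stages and not _manifest_path(out, dep).exists():
                raise PipelineError(
                    f"stage {stage!r} requires {dep!r}; run that stage first"
                )
        inputs = [config.resolve("markers"), config.resolve("scene")]
        if config.target_markers is not None:
            inputs.append(config.resolve("target_markers"))
        if config.margins is not None:
            inputs.append(config.resolve("margins"))
        signature = _stage_signature(config, stage, inputs)
        if not force and _up_to_date(out, stage, signature):
            log.info("stage %s up to date; skipping", stage)
            report[stage] = {"status": "skipped", "outputs": []}
            continue
        log.info("running stage %s", stage)
        outputs = _STAGE_FUNCS[stage](config, out)
        _write_manifest(out, stage, signature, outputs)
        report[stage] = {"status": "ran", "outputs": outputs}
    return report
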