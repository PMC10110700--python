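"""Gaze statistics of a synthetic pursuit in two coordinate systems.

Reconstructs a short pursuit from emitted marker data, renders the target's
semantic footprint from (i) the calibrated visual coordinate system and
(ii) the counterfactual trajectory coordinate system (forward axis along
the head's velocity), and compares how well the target is held in the
frontal ±10° longitude / −10°..4° latitude band.
"""

import numpy as np

from birdgaze.calibration import (
    calibrate_point_fixation,
    trajectory_track,
    visual_track,
)
from birdgaze.camera import CameraGrid
from birdgaze.gaze import angular_extents, fixation_summary, semantic_heatmap
from birdgaze.render import render_frame
from birdgaze.rigid_pose import (
    build_pose_track,
    fit_rigid_template,
    head_velocity,
    interpolate_poses,
)
from birdgaze.synth import make_pursuit_trial

trial = make_pursuit_trial(seed=3, duration=0.75, dropout_p=0.02)
tpl = fit_rigid_template(trial.headpack_markers)
track = interpolate_poses(build_pose_track(trial.headpack_markers, tpl))
vt = calibrate_point_fixation(track, trial.calibration_window,
                              trial.calibration_point)
cameras = {
    "visual": visual_track(track, vt),
    "trajectory": trajectory_track(track, vt, head_velocity(track)),
}

grid = CameraGrid(resolution=1.0)
target_id = max(trial.scene.labels())
for name, cam in cameras.items():
    frames = trial.flight_window
    stack = np.zeros((len(frames),) + grid.shape, dtype=np.uint8)
    flags = []
    for k, pos in enumerate(frames):
        flags.append(cam.status[pos])
        if cam.poses[pos] is not None:
            rf = render_frame(trial.scene, cam.poses[pos], grid,
                              frame=int(cam.frame_index[pos]))
            stack[k] = rf.semantic == target_id
    extents = angular_extents(stack, 1, grid, frame_flags=flags)
    frac = fixation_summary(extents)
    heat = semantic_heatmap(stack, 1, grid, frame_flags=flags)
    peak = np.unravel_index(np.argmax(heat.h), heat.h.shape)
    lon = grid.pixel_longitudes()[peak[1]]
    lat = grid.pixel_latitudes()[peak[0]]
    print(f"{name:>10}: fixation fraction {frac:.3f}; occupancy peak at "
          f"lon {lon:+.1f}°, lat {lat:+.1f}° (h = {heat.h.max():.1f})")

print("\nA fraction near 1 in the visual frame but not the trajectory frame "
      "shows the gaze is stabilised by rotational head movements, not by "
      "the flight path itself.")
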