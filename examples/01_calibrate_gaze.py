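"""Calibrate the head-fixed visual coordinate system from marker data.

A synthetic trial plays the role of a recording session: the bird sits on
the falconer's glove looking at a food morsel at a known position while the
head-mounted marker pack is tracked.  From the emitted (noisy) marker
clouds we fit a rigid body template, estimate per-frame poses, and recover
the fixed headpack→visual-frame rotation from the fixation assumption.
"""

import numpy as np

from birdgaze.calibration import calibrate_point_fixation, visual_track
from birdgaze.rigid_pose import build_pose_track, fit_rigid_template
from birdgaze.synth import make_pursuit_trial
from birdgaze.transforms import rotation_angle_deg

trial = make_pursuit_trial(seed=42, duration=0.5)
print(f"markers: {trial.headpack_markers.markers}, "
      f"noise σ = {trial.noise_sigma * 1e3:.1f} mm")

template = fit_rigid_template(trial.headpack_markers)
track = build_pose_track(trial.headpack_markers, template)
vt = calibrate_point_fixation(track, trial.calibration_window,
                              trial.calibration_point)
recovered = visual_track(track, vt)

errs = [rotation_angle_deg(p.rotation, q.rotation)
        for p, q in zip(recovered.poses, trial.head_track.poses)]
print(f"gaze-frame recovery error: median {np.median(errs):.3f}°, "
      f"max {max(errs):.3f}° over {len(errs)} frames")
print("The error is the angle between the reconstructed and the true "
      "visual coordinate system per frame; at sub-millimetre marker noise "
      "its median stays below one degree (outliers come from single noisy "
      "frames, not from the calibration itself).")
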