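"""Render a 360° egocentric view of the obstacle course.

Places the spherical camera mid-lab looking down the row of pillars and
reports what fraction of the visual sphere each scene element occupies,
split by the bird's visual-field regions (binocular / monocular / blind).
"""

import numpy as np

from birdgaze.camera import CameraGrid
from birdgaze.render import render_frame
from birdgaze.synth import make_lab_scene
from birdgaze.transforms import Transform
from birdgaze.visual_field import (
    RegionLabel,
    classify_directions,
    default_margin_table,
    interpolate_margins,
)

scene = make_lab_scene("obstacle")
grid = CameraGrid(resolution=1.0)
# mid-lab, gaze rotated to face +x — straight down the row of pillars
R = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
pose = Transform(R, [10.0, 3.0, 1.4])

rf = render_frame(scene, pose, grid)
A = grid.solid_angles()
labels = scene.labels()
print("solid-angle share of each scene element (whole sphere):")
for obj_id in np.unique(rf.semantic):
    share = A[rf.semantic == obj_id].sum() / (4 * np.pi)
    print(f"  {labels[int(obj_id)]:<12} {share * 100:5.1f} %")

regions = classify_directions(grid, interpolate_margins(default_margin_table()))
binoc = regions == RegionLabel.BINOCULAR
pillar_ids = [i for i, l in labels.items() if l.startswith("pillar")]
in_binoc = np.isin(rf.semantic, pillar_ids) & binoc
print(f"\npillars cover {A[in_binoc].sum() / A[binoc].sum() * 100:.2f} % "
      "of the binocular field from this pose")
print("Depth at the nadir:", f"{rf.depth[grid.height - 1, grid.width // 2]:.2f} m",
      "(camera height above the floor)")
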