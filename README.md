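# birdgaze

**Synthetic reconstruction of a bird's egocentric visual field from
motion-capture data.**

Head-mounted cameras are too heavy, too narrow and too wobbly to record what
a bird actually sees in flight. `birdgaze` takes the opposite route: track
the head with marker-based motion capture, build a registered 3D model of
the flight environment, and *render* the bird's view synthetically — a full
360° spherical camera with per-pixel depth, semantic labels, RGB and optic
flow, at the full motion-capture rate, with the species' binocular,
monocular and blind regions overlaid. It is written for researchers in
visually guided flight, active vision and visuomotor control who have (or
can simulate) rigid-body tracking of an animal's head.

## What it computes

**Head pose.** A rigid marker pack on the head gives, per frame, a
least-squares rigid registration (Kabsch absolute orientation) of a fitted
body template; frames with fewer than three reconstructed markers are
marked missing and short gaps are filled by geodesic interpolation on
SO(3).

**Visual coordinate system.** The marker pack sits arbitrarily on the head,
so the fixed headpack→visual rotation `T_H^V` is calibrated behaviourally:
during a window in which the bird is known to look at a point (food on the
glove; the perch centre on landing) with its eyes held level, each frame
yields a candidate rotation, and the candidates are averaged by chordal
mean. A counterfactual *trajectory coordinate system* — forward axis along
the head's velocity `v`, x-axis horizontal — isolates what the view would
be without rotational head movements.

**Scene.** A hybrid lab model: planes for floor/walls/ceiling (walls from
the motion-capture camera positions), cylinders for obstacles and perches,
cones for pulleys, cuboids for boxes, and triangle meshes for complex
objects, registered into the motion-capture frame through the three marker
corners of a fiducial plate and re-levelled onto the floor plane.

**Rendering and flow.** An in-repo ray caster samples an equirectangular
grid (default 5 px/°) of viewing directions. Optic flow on the unit sphere
comes either from the instantaneous rigid-scene motion field

```
ḋ = −Ω × d + ((v·d) d − v) / r
```

or from reprojecting rendered hit points between consecutive frames
(which also covers independently moving objects); speeds are reported in
deg/s per pixel.

**Gaze statistics.** The central statistic is the solid-angle-normalised
occupancy heatmap

```
h_i = n_i / (N · A_i)
```

(`n_i` frames in which pixel *i* saw the label, `N` analysed frames, `A_i`
the pixel's solid angle normalised by the maximum), plus per-frame target
contours, seam-safe angular extents, occlusion intervals against an
occluder-free reference render, and fixation-band summaries.

No flight recordings ship with the package; a first-class synthetic-trial
generator (`birdgaze.synth`) emulates the experimental setup — a
20 × 6 × 3.3 m lab at 200 Hz, a 5-marker head pack with 0.3 mm noise and
dropout, a towed target dragged around pulleys at 5.6 m/s, scripted
fixating gaze with wingbeat-induced head bobbing — and returns the ground
truth for every quantity the pipeline estimates.

## Worked example

```sh
python examples/04_pursuit_gaze_statistics.py
```

```
    visual: fixation fraction 1.000; occupancy peak at lon -0.5°, lat +0.5° (h = 0.3)
trajectory: fixation fraction 0.000; occupancy peak at lon +47.5°, lat -43.5° (h = 0.0)
```

On a synthetic pursuit with a fixating gaze program, the target's full
angular extent stays inside the frontal ±10° longitude / −10°..4° latitude
band in every analysed frame of the *visual* coordinate system, and
essentially never in the *trajectory* coordinate system — the signature of
gaze stabilisation by rotational head movements rather than by the flight
path. The occupancy peak sits on the gaze axis in the visual frame and
tens of degrees off-axis in the trajectory frame.

The other examples calibrate the visual frame from noisy markers
(`01_calibrate_gaze.py`), render the obstacle course and report
solid-angle shares per scene element (`02_render_egocentric_view.py`), and
compare the two optic-flow routes (`03_optic_flow.py`).

A thin CLI wraps the same pipeline for shell use:

```sh
birdgaze simulate --out-dir scratch/demo --seed 1 --resolution 1 --camera both
birdgaze calibrate   --config scratch/demo/trial.yaml
birdgaze build-scene --config scratch/demo/trial.yaml
birdgaze render      --config scratch/demo/trial.yaml
birdgaze analyze     --config scratch/demo/trial.yaml
birdgaze report      --config scratch/demo/trial.yaml
```

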