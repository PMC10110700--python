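# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `birdgaze`, and what the synthetic-data tests do
and do not establish about real recordings.

## Coordinate systems and conventions

All positions are metres in a z-up motion-capture world frame with the
floor at z = 0. A `Transform` is the proper rigid map `T_A^B` taking
coordinates in frame A to frame B; rotations are stored as 3×3 matrices
and interpolated along the SO(3) geodesic via the axis–angle of the
relative rotation, which avoids quaternion sign ambiguities.

The visual/camera frame is right-handed with **y = forward (gaze),
x = right, z = dorsal**. The spherical chart uses longitude
λ ∈ [−180°, 180°) positive toward +x and latitude φ ∈ [−90°, 90°] positive
toward +z, with `direction(0,0) = (0,1,0)`. Equirectangular rasters put
pixel centres at half-integer offsets so the image centre is the forward
direction; the per-row solid angle is `Δλ·(sin φ_top − sin φ_bottom)`,
which tiles the sphere exactly (Σ A = 4π to machine precision). Note that
with an even number of rows no pixel band straddles the equator; the
maximal solid angle is attained on the two rows adjacent to it.

## Rigid pose from marker clouds

Pose estimation is Kabsch absolute orientation on the present markers
(centroid subtraction, SVD of the cross-covariance, determinant correction
to force a proper rotation), with the residual RMS reported. Frames with
fewer than three present markers, or a collinear present subset (second
singular value ≤ 1e−6 m), are unrecoverable and marked `missing`.

Body templates are fitted from frames with all markers present: the body
frame's origin is the marker centroid and its axes the principal axes of
the configuration. The sign of each principal axis is fixed by a
shape-intrinsic rule — the marker projection of largest magnitude along
the axis is made positive — so the same physical cloud yields the same
template in any pose. Same-frame ghost markers closer than 1 mm are
collapsed to their mean before fitting.

Gap filling: gaps of ≤ `max_gap` frames (default 10, i.e. 50 ms at 200 Hz)
between measured frames are filled with linear translation and geodesic
rotation interpolation and flagged `interpolated`; longer gaps stay
missing. The default spans a typical dropout burst without inventing long
motions. Head velocity is a central difference smoothed by a 5-frame
moving average (odd window; endpoints one-sided) — enough to suppress
per-frame jitter while passing wingbeat-frequency content.

## Calibrating the visual coordinate system

Three behavioural assumptions identify the fixed headpack→visual rotation:
gaze movements are executed by the head (eye-in-head movement neglected);
during the calibration window the gaze target is known (a fixated world
point); and the eyes are held level. Each measured window frame gives
forward = unit vector from the visual-frame origin to the target, the
eyes-level constraint fixes roll (right = forward × world-up), and the
candidate rotation is pulled back into the headpack frame. Candidates are
averaged by **chordal mean** (arithmetic matrix mean projected onto SO(3)
by SVD) — deterministic and adequate at the sub-degree spreads involved.
Whether one averages candidate rotations or fits once to averaged vectors
is immaterial at this spread; the chordal mean was chosen for simplicity.
Frames where the target direction is parallel to world-up are excluded.

The visual-frame origin defaults to the headpack centroid (zero offset).
The ideal origin — the midpoint between the eyes — cannot be identified
from the marker data alone, so the offset is an explicit, overridable
parameter.

The **trajectory coordinate system** is y = v̂ (head velocity),
x = v̂ × world-up normalised (horizontal by construction), z = x × y,
origin at the visual-frame origin. Frames with speed below 1e−3 m/s or
near-vertical velocity are degenerate; the track holds the previous
frame's orientation there (leading degenerate frames take the first valid
one).

## Visual-field regions

Each eye's field is a pair of margin curves (upper/lower elevation vs
longitude), periodic and piecewise-linear in longitude; `upper ≤ lower`
encodes arcs the eye does not see. A direction is binocular, monocular or
blind according to how many eyes see it. The forward direction is the
longitude of maximum binocular vertical extent (fine grid search, ties
toward 0°), which is how imported tables are re-centred.

The packaged table is **synthetic**: a parametric approximation with a
frontal binocular sector ~36° wide of ~100° vertical extent, large lateral
monocular lobes, a 60° caudal blind sector and a dorsal blind cap — the
qualitative layout reported for Harris' hawks — generated by
`build_synthetic_margin_table` and shipped as CSV. It is *not* a
digitisation of published ophthalmoscopy figures; any user-measured table
in the same format drops in.

## Scene model

Floor/walls/ceiling are planes (walls = axis-aligned bounding planes of
the motion-capture camera positions pushed outward by a configurable
margin, default 0 m — how far real cameras sit from real walls is
rig-specific and deliberately not guessed). Obstacles and perches are
finite capped cylinders, pulleys cones, boxes cuboids; their parameters
come from attached markers plus measured dimensions through documented
per-kind constructions. The towed target is a cylinder (length 0.15 m,
diameter 0.025 m) carried in its body frame and posed per frame from its
own marker track.

Scanned meshes are registered into the motion-capture frame via the three
marker corners of a fiducial plate: an auxiliary orthonormal frame is
built from the ordered triple in each coordinate system (origin = corner 1,
x toward corner 2, z = triangle normal oriented by vertex order) and the
transform is the composition — exact for rigid pairs; non-rigid triples
fall back to a 3-point least-squares fit with a reported residual. The
fixed corner ordering removes a silent 180° ambiguity, so plate files must
list corners consistently. Mesh floors are re-levelled by fitting a
total-least-squares plane to a z-band of vertices and applying the minimal
rotation onto the target plane; the pre-correction tilt (degrees) and
post-correction residual are reported. Mesh cleaning (duplicate-vertex
merge, degenerate-face removal, small-component removal with a
triangle-count threshold) uses `trimesh`.

## Rendering

The renderer is a deterministic ray caster over the equirectangular grid:
closed-form intersections for planes, capped cylinders and cones, and
oriented boxes (slab test), and chunked vectorised Möller–Trumbore for
triangle meshes, with a 1e−6 m self-hit guard. Nearest-hit ties break
toward the lowest object id; coincident geometry is a modelling error, not
a rendering feature. RGB is a flat per-label colour (no shading, shadows
or textures — presentation extras that carry no information the semantic
and depth rasters don't already hold).

## Optic flow

Flow is defined as the motion of *scene points* across the unit sphere of
viewing directions (positive speed = image motion), reported per pixel in
deg/s. Two routes:

- the analytic rigid-scene motion field `ḋ = −Ω×d + ((v·d)d − v)/r`,
  valid for a static scene, with the translational term zero at infinite
  range (background moves only under rotation);
- finite-difference reprojection: each hit point is advected by its
  object's rigid motion between frames k and k+1 (identity for statics),
  re-expressed in both camera frames, and the great-circle angle between
  the old and new directions — scaled by the sample rate and projected
  onto the tangent plane at the old direction — gives the flow vector.

The two agree to first order in the frame interval on static scenes (the
test suite verifies the ~linear error decay over 5/2.5/1.25 ms); the
reprojection route additionally covers the moving target. Display caps of
[10, 1000] deg/s on a log scale are a visualisation convention only and
never touch stored values.

## Gaze statistics

`h_i = n_i/(N·A_i)` with `A_i` the normalised per-pixel solid angle; `N`
counts only frames whose head transform was *measured* (interpolated
frames are excluded, as are frames outside a user window, e.g. after
interception), and the analysis is restricted to the visible part of the
visual field in the visual coordinate system. Angular extents per frame
use the minimal covering arc modulo 360° in longitude (seam-safe) and
plain min/max in latitude; interpolated frames are flagged rather than
dropped so they can be drawn distinctly. Because a per-frame "mean"
position can reasonably mean either the interval midpoint or the
area-weighted centroid, both are emitted as separate, explicitly named
columns. Occlusion classification compares the solid-angle-weighted label
area against an occluder-free reference render of the same poses: ratio
≥ 0.98 → fully visible, 0 < ratio < 0.98 → partially occluded, 0 → not
visible (the 2 % tolerance absorbs raster discretisation at region
boundaries). Head saccade detection is deliberately not automated; the
per-frame extents and pose tracks support visual inspection instead.

## Synthetic trials

The generator emulates the study conditions rather than idealising them:
a 20 × 6 × 3.3 m lab sampled at 200 Hz; a rigid 5-marker head pack of
~6 cm span with isotropic Gaussian marker noise (σ default 0.3 mm, typical
of optical motion capture) and independent per-marker dropout; a 3-marker
towed target dragged around a pulley circuit at a mean 5.6 m/s (fillet
arcs at the corners, constant-speed arc-length parametrisation); pillars
of height 2 m and diameter 0.3 m and perches 9 m apart in the obstacle
preset; a floor-to-ceiling curtain with a ~1.05 m gap in the pursuit
preset. The pursuit flight lasts 2.5 s (500 frames) after a 50-frame
stationary calibration segment in which the head fixates a known food
point.

The wingbeat enters in either of two ways, both exposed: as a pitch
sinusoid on the head *orientation* (default 4 Hz), or as vertical head
*bobbing* (default 2 cm at the wingbeat frequency) combined with a gaze
program that keeps fixating the target — the latter is the configuration
used for the coordinate-system contrast, since a gaze-stabilising bird
cancels the wingbeat in its visual frame while the velocity vector (and
hence the trajectory frame) keeps oscillating. Trials are deterministic
given their seed (NumPy PCG64).

What the generator does **not** emulate: soft-tissue marker movement,
non-isotropic or distance-dependent mocap noise, correlated dropout from
occlusion geometry, aerodynamics or biomechanics of real flight, eye
movements, and photorealistic appearance. Passing tests therefore
establish the correctness of the reconstruction and analysis machinery
under realistic noise magnitudes — not that a real bird behaves like the
scripted gaze programs.

## Problem sizes and tolerances

The test suite and the acceptance script run the pursuit contrast at
1 px/° over the full 500-frame flight in both coordinate systems, and the
renderer/flow oracles at 1 px/° — resolutions at which the statistics of
interest (fixation fractions, spectral peaks, extents) are already stable;
5 px/° reproduces the same numbers at proportionally higher cost and is
the default for production renders. Exact geometric identities (pose and
plate recovery, depth closed forms, solid-angle conservation) are asserted
at 1e−9; statistical recoveries at tolerances fixed by independent
Monte-Carlo oracles (e.g. gaze calibration ≤ 1° at 0.5 mm marker noise
with a 50-frame window).

## Known limitations

- Uniform angular resolution; no foveal (acuity-weighted) sampling.
- Monocular camera model: vergence and stereo are out of scope.
- The visual-frame origin is the headpack centroid unless the user
  supplies an eye-midpoint offset.
- The packaged margin table is a synthetic approximation, not species
  measurement data.
- The ray caster has no acceleration structure beyond chunked
  vectorisation; very large meshes render slowly.
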