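# Methods

## Pipeline model and assumptions

The pipeline assumes a single labeled crop plant per frame, an arbitrary
number (1–6) of unlabeled weeds, controlled illumination, and a conveyor
moving plants past a fixed sensor/camera rig. Processing order is fixed:
fuse sensor events → HSV segmentation → morphological opening →
connected components → tolerance zone → crop/weed classification.

**Coordinates.** Image coordinates are (x = column, y = row), origin at
the top-left pixel; travel is along +y. The mapping of image axes onto
the belt is a convention, not a measurement — `SensorArray(mirror=True)`
swaps the axes for rigs wired the other way.

**Fusion.** Trigger pairs on the same detection line are structurally
invalid (their beams sweep the same line, so they carry no intersection).
`select_signal` scans ordered event pairs lexicographically and fuses the
first valid one; the gap `dt` is the interval between the two triggers of
that pair, the only time quantity two events define. Simultaneous events
are ordered by ascending sensor id — an arbitrary but deterministic
tie-break that never changes the estimate, because line-mates are
interchangeable in the case table. Estimates are rounded to the nearest
integer pixel with ties away from zero, then clamped to the frame and
flagged when clamping fired (a clamped estimate means the gap implies a
point outside the camera's view).

**Segmentation.** Hue lives on the 8-bit halved-degree scale (0–179),
the dominant convention for 8-bit HSV; a `full_degrees` switch accepts
0–359 bands. All six band edges are inclusive. The HSV conversion is the
standard hexcone formula; V is the channel maximum ("value", even where
practitioners loosely say luminance).

**Morphology.** One erosion followed by one dilation with the 3×3 square
element. Pixels outside the frame count as background for erosion and
contribute nothing in dilation (zero-padding); foreground touching the
border is therefore eroded at the border like anywhere else. Opening is
idempotent and anti-extensive — both are asserted as properties.

**Components.** 8-connectivity (diagonal contact joins regions), via
`scipy.ndimage.label`. A component's contour is its pixels with at least
one background 4-neighbor or on the image edge, so interior holes
contribute their own boundary rings; contours are reported in row-major
order, not traced as a closed path. Components are ordered by descending
area, ties by the topmost-leftmost pixel.

**Classification.** The tolerance disc is boundary-inclusive (distance ≤
radius counts), with real-valued radius `radius_mm × px_per_mm`. Every
intersecting component is crop; since scenes contain one crop plant,
multiple intersections are rare, and a `nearest-centroid` mode that
labels only the intersecting component nearest the zone center is
available for crowded scenes. With no valid fused signal every region is
weed: a missed detection degrades gracefully instead of erroring.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `center` | 360 px | frame center; all fusion loci pass through (360, 360) |
| `speed_px_s` | 400 px/s | conveyor speed in image space; with 4 px/mm this is 100 mm/s, the order of a slow vegetable-bed conveyor |
| `h/s/v` bands | [10,120], [10,255], [10,255] | plant acceptance region in HSV |
| `radius_mm` | 7.5 mm | tolerance radius; the optimum in both the physical trial and the desync experiment |
| `px_per_mm` | 4 (0.25 mm/px) | image scale; physical-unit radii require it, so it is an explicit config value |
| `match_radius_px` | 60 px | scoring: a truth plant is detected iff a component of the right class has its centroid within this radius (≈ crop canopy extent) |

## Synthetic scenes

`generate_scene` emulates a 720×720 top-view frame: a soil background
with per-pixel HSV noise, one crop canopy (2–5 overlapping ellipses,
semi-axes 18–40 px, around the stem), and 1–6 single-ellipse weeds
(semi-axes 8–22 px). Plant colors are drawn from H ∈ [35,75],
S ∈ [130,230], V ∈ [100,220] — strictly inside the acceptance bands —
and soil from H ∈ [2,7], S ∈ [40,140], V ∈ [50,150], strictly outside.
The margins are wide enough that 8-bit HSV→RGB→HSV quantization cannot
cross a threshold: enumerating the full soil band shows the round-trip
hue never exceeds 9 (threshold 10), and the plant band round-trips inside
all three bands. Segmentation of a clean scene is therefore *exactly* the
plant mask, which is asserted per scene in the tests.

The label point is placed on a fusion locus (offset d ∈ [0, 250] px,
locus chosen uniformly among the three, the vertical locus splitting its
sign evenly), and the event stream is generated by the exact algebraic
inverse of the fusion case table: both sensors of the first line fire at
t = 0, both sensors of the second at t = dt. This makes fusion exactly
round-trippable — the simulator is *defined* as the inverse of the
localization rule, since physical inter-sensor distances are a property
of a particular rig, not of the algorithm. Occlusion drops each active
sensor's event independently with probability `occlusion_p`; the uniform
draw for sensor s depends only on (seed, s), so nested sensor subsets and
different occlusion levels see common random numbers and per-scene
monotonicity holds exactly, not just in expectation.

Weed placement is uniform over the frame by default, with rejection
retries enforcing minimum separations (crop–weed 150 px, weed–weed
60 px; weed masks can never merge since 2×22 < 60). The
`around_crop` mode instead draws weeds area-uniformly from an annulus
(80–250 px) around the stem, emulating a transplant bed where weeds
crowd the crop. Per-scene child seeds are `master_seed + scene_index`.

**What the simulator does not emulate:** leaf texture and shape,
illumination gradients, specular soil residue, overlapping crop/weed
canopies, and sensor optics (reflectance calibration, beam width). A
passing suite therefore demonstrates the correctness of the *algorithmic*
contracts — fusion geometry, threshold logic, morphology, zone
classification, accuracy arithmetic — not field robustness of the
thresholds themselves, which on real images depend on illumination.

## Experiments

**Desynchronization sweep.** `desync_config()` displaces the plants
relative to the label point by up to 60 px, uniform in direction and
radius: at the rig's conveyor speed (~253 mm/s) and 30 ms frame period, a
two-frame latency between trigger and exposure is ≈15 mm ≈ 60 px at
4 px/mm. Combined with `around_crop` weeds, small tolerance radii miss
the displaced crop and large radii swallow nearby weeds, so the sweep
over {2.5, 5, 7.5, 10, 12.5} mm shows rising crop accuracy, falling weed
accuracy, and a hump-shaped overall accuracy peaking mid-sweep. The
monotone directions are deterministic (disc growth is a superset
operation, and greedy one-to-one matching can only gain matches when a
class gains candidates); only the magnitudes are stochastic. The
acceptance run uses 200 scenes, the example script 60 — sizes chosen so
the whole sweep stays well under a minute while the per-class counts
(hundreds of weeds) make the trend visible.

**Sensor-count experiment.** 500 truth-level scenes (no rendering
needed), per-sensor occlusion 0.4, subsets {2,5} ⊂ {1,2,4,5} ⊂ all six.
One line can never validate (rate exactly 0); two lines detect only
scenes whose locus their lines can express; three lines detect whenever
each involved line keeps one surviving sensor. With no occlusion the full
array detects every label. This reproduces the ordering observed on the
physical rig (20.67% < 63.33% < 100%); the simulated magnitudes depend on
the occlusion probability, which the physical trial did not measure.

**Error-free limit.** Under default (clean) conditions — no occlusion,
no desync, separations ≥ canopy + weed + largest disc — the pipeline is
exact end-to-end: 100% crop and weed accuracy at 7.5 mm. Any failure
here indicates a logic regression, not noise.

## Numerical choices and edge cases

- Percentage reporting rounds half away from zero to 2 decimals; raw
  counts are kept and all aggregation happens on counts, never on
  rounded percentages. (The trial's tabulated weed accuracy at 7.5 mm is
  internally inconsistent in its last digit; 1052/1114 prints as 94.43
  under this rule, and the raw counts are treated as authoritative
  throughout.)
- The fusion inverse maps the center point (c, c) to the (B, C) case
  with d = 0; any valid pair reproduces it, so the choice is free and
  fixed for determinism.
- The two half-gap fusion cases (A→C, C→A) round each coordinate
  independently, so an odd gap can land one pixel off the exact
  anti-diagonal; tests assert exactness for even gaps and a 1 px bound
  for odd ones. Round-trip tests use the (A,B)/(B,·)/(C,B) cases, which
  are integer-exact.
- Scenes where generation cannot place a weed after 100 retries raise a
  generation error rather than silently relaxing separations.

## Known limitations

- Overlapping plants form one component and are classified jointly;
  separating touching canopies is out of scope.
- The segmentation thresholds are fixed, not illumination-adaptive.
- `SceneTruth` persisted to JSON keeps centroids and bounding boxes but
  not pixel masks; mask-level checks require regenerating the scene.
- The event-time model places both sensors of a line at the same
  timestamp; real line-mates would be offset by their physical spacing,
  which the algorithm never uses.
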