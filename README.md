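# cropsignal

Crop-signaling weed/crop discrimination for precision weeding, in pure
Python. The setting: transplanted vegetable crops (e.g. tomato) carry a
machine-readable label — a white topical marker on the lower stem — while
weeds do not. A conveyor rig combines a top-view color camera with six
photoelectric color-mark sensors; the sensors detect the label and
*localize* it, the camera image separates all plants from the soil, and a
tolerance zone around the estimated label position decides which plant
region is the crop. Everything else is a weed, yielding a prescription map
(crop red, weeds green) for targeted weeding.

`cropsignal` implements this pipeline as a library plus a thin CLI, with a
synthetic conveyor-scene simulator in place of the physical hardware.

## The model

**Sensor fusion.** Sensors 1/4, 2/5 and 3/6 sweep three detection lines
*A*, *B*, *C* in image space (B parallel to travel, A and C at ±45°). A
detection is valid only when two sensors on *distinct* lines fire. For the
earliest valid ordered pair with trigger gap *dt* and conveyor speed *v*
(px/s), writing *d = dt·v* and *c* = 360 for the frame center, the label
position is the intersection of the two lines:

| first → second line | estimate (x, y) |
|---|---|
| A → B | (c−d, c−d) |
| A → C | (c−d/2, c−d/2) |
| B → A | (c, c+d) |
| B → C | (c, c−d) |
| C → A | (c−d/2, c+d/2) |
| C → B | (c−d, c+d) |

Every estimate lies on the main diagonal, the vertical center line, or the
anti-diagonal through (c, c). The simulator exposes the exact algebraic
inverse of this table, so fusion is testable by round-trip.

**Segmentation.** The RGB frame is converted to HSV (hue on the 8-bit
0–179 halved-degree scale) and a pixel is plant iff

H ∈ [10, 120] and S ∈ [10, 255] and V ∈ [10, 255]

(all bands closed, configurable). The binary mask is opened with a 3×3
square structuring element (one erosion, one dilation) and maximal
8-connected regions are extracted with contour, centroid and area.

**Classification.** A disc of radius *r* mm (default 7.5 mm; scale
4 px/mm) is drawn around the fused label position. Every region with a
pixel inside the disc is crop; the rest are weeds. Per-class accuracy is
`100·correct/total`, and the overall accuracy pools both classes:

overall = 100 · (crop_correct + weed_correct) / (crop_total + weed_total).

## Worked example

```sh
python examples/tolerance_radius_sweep.py
```

runs the full pipeline on 60 synthetic scenes under shutter
desynchronization (the plants travel up to ~60 px between sensor trigger
and camera exposure, and weeds crowd the crop) and prints:

```
 radius_mm  crop_accuracy  weed_accuracy  overall_accuracy
       2.5          75.00         100.00             94.30
       5.0          93.33          99.51             98.10
       7.5         100.00          99.01             99.24
      10.0         100.00          98.03             98.48
      12.5         100.00          97.04             97.72
```

Small discs miss the displaced crop (crop accuracy 75% at 2.5 mm); large
discs swallow nearby weeds (weed accuracy falls to 97%); the overall
accuracy peaks at an intermediate radius — here 7.5 mm, the same optimum
reported for the physical rig. The monotone columns are a theorem, not a
coincidence: growing the disc can only move regions from weed to crop.

`examples/` holds one short script per capability: event fusion
(`fuse_sensor_events.py`), the end-to-end pipeline on one scene
(`segment_and_classify.py`), the radius sweep above, and the
sensor-count/occlusion experiment (`sensor_count_experiment.py`).

The same workflows are available from a shell:

```sh
cropsignal simulate --n-scenes 20 --seed 1 --out-dir data/
cropsignal detect --image data/scene_0000.png --events data/events_0000.json --out-dir out/
cropsignal evaluate --dataset data/ --radii 2.5,5,7.5,10,12.5 --out-dir report/
cropsignal sweep-sensors --n-scenes 500 --occlusion-p 0.4 --out-dir report/
```

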