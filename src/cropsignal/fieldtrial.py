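"""Published detection counts from the physical conveyor trials.

These are the raw correct/total counts reported for the hardware rig
(color mark sensors on a conveyor with 300 labeled tomato plants and
1114 unlabeled pakchoi "weeds").  They are inputs to the accuracy
arithmetic in :mod:`cropsignal.evaluate`: the package recomputes every
percentage from these counts rather than restating printed percentages.
"""

from __future__ import annotations

#: Label-recognition trials: (sensor reference, physical label color)
#: -> (samples, correct detections).
LABEL_REFERENCE_TRIALS: dict[tuple[str, str], tuple[int, int]] = {
    ("weed_stem", "red"): (300, 73),
    ("weed_stem", "white"): (300, 206),
    ("weed_stem", "green"): (300, 0),
    ("tomato_stem", "red"): (300, 166),
    ("tomato_stem", "white"): (300, 274),
    ("tomato_stem", "green"): (300, 0),
}

#: Tolerance-zone trials: radius in mm -> per-class (correct, total)
#: counts as {"crop": (correct, total), "weed": (correct, total)}.
TOLERANCE_TRIALS: dict[float, dict[str, tuple[int, int]]] = {
    2.5: {"crop": (267, 300), "weed": (1063, 1114)},
    5.0: {"crop": (291, 300), "weed": (1054, 1114)},
    7.5: {"crop": (294, 300), "weed": (1052, 1114)},
    10.0: {"crop": (295, 300), "weed": (1050, 1114)},
    12.5: {"crop": (300, 300), "weed": (1044, 1114)},
}

#: Detection rates by sensor count reported for the physical rig (for
#: qualitative comparison with the in-silico occlusion experiment).
SENSOR_COUNT_FIELD_RATES: dict[int, float] = {2: 20.67, 4: 63.33, 6: 100.0}
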