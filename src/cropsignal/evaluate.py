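"""Accuracy arithmetic, scene scoring, and in-silico experiments.

Per-class accuracy is ``100 * correct / total``; the overall accuracy
pools both classes::

    overall = 100 * (crop_correct + weed_correct) / (crop_total + weed_total)

i.e. the count-weighted mean of the class accuracies.  Percentages are
reported to 2 decimals (round half away from zero), matching how such
trials are conventionally tabulated; raw counts are retained.

Scene scoring replaces human inspection with a stated rule: a ground-
truth plant counts as correctly detected iff some predicted component
of the matching class has its centroid within ``match_radius_px`` of
the truth centroid, under greedy one-to-one matching by ascending
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationResult, make_zone, classify_components
from .errors import DomainError
from .fusion import SensorArray, SensorEvent, select_signal
from .simulate import SceneTruth, simulate_sensor_events
from .vision import HsvThresholds, extract_components, open_mask, rgb_to_hsv, segment

__all__ = [
    "AccuracyReport",
    "per_class_accuracy",
    "overall_accuracy",
    "mean_accuracy",
    "score_scene",
    "run_pipeline",
    "sweep_tolerance",
    "sensor_count_experiment",
]


def _round2(x: float) -> float:
    """Two-decimal reporting, ties away from zero (97.005 -> 97.01)."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def per_class_accuracy(correct: int, total: int) -> float:
    """Percentage of correctly detected samples in one class."""
    if total <= 0:
        raise DomainError(f"total must be > 0, got {total}")
    if not 0 <= correct <= total:
        raise DomainError(f"correct must be in [0, {total}], got {correct}")
    return _round2(100.0 * correct / total)


def overall_accuracy(
    crop_correct: int, crop_total: int, weed_correct: int, weed_total: int
) -> float:
    """Pooled accuracy over crop and weed samples."""
    if crop_total + weed_total <= 0:
        raise DomainError("combined total must be > 0")
    for correct, total in ((crop_correct, crop_total), (weed_correct, weed_total)):
        if not 0 <= correct <= total:
            raise DomainError(f"correct={correct} outside [0, {total}]")
    return _round2(100.0 * (crop_correct + weed_correct) / (crop_total + weed_total))


def mean_accuracy(accuracies: Sequence[float]) -> float:
    """Arithmetic mean of percentages (pooled accuracy when totals are equal)."""
    if len(accuracies) == 0:
        raise DomainError("accuracies must be non-empty")
    return _round2(float(np.mean(accuracies)))


@dataclass(frozen=True)
class AccuracyReport:
    """Correct/total counts per class with derived percentages."""

    crop_correct: int
    crop_total: int
    weed_correct: int
    weed_total: int

    @property
    def crop_accuracy(self) -> float:
        return per_class_accuracy(self.crop_correct, self.crop_total)

    @property
    def weed_accuracy(self) -> float:
        return per_class_accuracy(self.weed_correct, self.weed_total)

    @property
    def overall(self) -> float:
        return overall_accuracy(
            self.crop_correct, self.crop_total, self.weed_correct, self.weed_total
        )

    def __add__(self, other: "AccuracyReport") -> "AccuracyReport":
        return AccuracyReport(
            self.crop_correct + other.crop_correct,
            self.crop_total + other.crop_total,
            self.weed_correct + other.weed_correct,
            self.weed_total + other.weed_total,
        )


def _greedy_match(truth_pts: list[tuple[float, float]],
                  pred_pts: list[tuple[float, float]],
                  radius: float) -> int:
    """Count one-to-one matches within ``radius``, nearest pairs first."""
    pairs = [
        (np.hypot(t[0] - p[0], t[1] - p[1]), i, j)
        for i, t in enumerate(truth_pts)
        for j, p in enumerate(pred_pts)
    ]
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    n = 0
    for dist, i, j in pairs:
        if dist > radius:
            break
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        n += 1
    return n


def score_scene(
    result: ClassificationResult, truth: SceneTruth, match_radius_px: float
) -> AccuracyReport:
    """Score one scene's classification against its ground truth."""
    crop_pred = [c.centroid for c in result.by_class("crop")]
    weed_pred = [c.centroid for c in result.by_class("weed")]
    crop_correct = _greedy_match([truth.crop_centroid], crop_pred, match_radius_px)
    weed_correct = _greedy_match(list(truth.weed_centroids), weed_pred, match_radius_px)
    return AccuracyReport(crop_correct, 1, weed_correct, truth.n_weeds)


def run_pipeline(
    image: np.ndarray,
    events: Sequence[SensorEvent],
    array: SensorArray,
    thresholds: HsvThresholds | None = None,
    radius_mm: float = 7.5,
    px_per_mm: float = 4.0,
    *,
    mode: str = "intersect",
) -> ClassificationResult:
    """Run the full detection pipeline once on one scene.

    Order: fuse events -> HSV segmentation -> morphological opening ->
    connected components -> tolerance zone -> crop/weed classification.
    A missing valid sensor pair yields ``zone=None`` and an all-weed
    classification (a missed detection, not an error).
    """
    signal = select_signal(list(events), array)
    mask = open_mask(segment(rgb_to_hsv(image), thresholds))
    components = extract_components(mask)
    zone = (
        make_zone(signal.point, radius_mm, px_per_mm) if signal is not None else None
    )
    return classify_components(components, zone, mode=mode)


def sweep_tolerance(
    scenes: Iterable[tuple[np.ndarray, SceneTruth, Sequence[SensorEvent]]],
    radii_mm: Sequence[float],
    array: SensorArray,
    *,
    thresholds: HsvThresholds | None = None,
    px_per_mm: float = 4.0,
    match_radius_px: float | None = None,
    mode: str = "intersect",
) -> pd.DataFrame:
    """Aggregate accuracies over a dataset for each tolerance radius.

    The fused signal, segmentation and components are computed once per
    scene and shared across radii (only the zone radius changes), so
    every radius sees identical inputs.  Returns one row per radius
    with counts, class accuracies and overall accuracy.
    """
    if not radii_mm or any(r <= 0 for r in radii_mm):
        raise DomainError("radii_mm must be non-empty and positive")
    if match_radius_px is None:
        match_radius_px = 60.0  # ~ crop canopy extent at defaults
    totals = {r: AccuracyReport(0, 0, 0, 0) for r in radii_mm}
    n_scenes = 0
    for image, truth, events in scenes:
        n_scenes += 1
        signal = select_signal(list(events), array)
        mask = open_mask(segment(rgb_to_hsv(image), thresholds))
        components = extract_components(mask)
        for r in radii_mm:
            zone = (
                make_zone(signal.point, r, px_per_mm) if signal is not None else None
            )
            result = classify_components(components, zone, mode=mode)
            totals[r] = totals[r] + score_scene(result, truth, match_radius_px)
    if n_scenes == 0:
        raise DomainError("dataset is empty")
    rows = [
        {
            "radius_mm": r,
            "crop_correct": rep.crop_correct,
            "crop_total": rep.crop_total,
            "weed_correct": rep.weed_correct,
            "weed_total": rep.weed_total,
            "crop_accuracy": rep.crop_accuracy,
            "weed_accuracy": rep.weed_accuracy,
            "overall_accuracy": rep.overall,
        }
        for r, rep in totals.items()
    ]
    return pd.DataFrame(rows)


def sensor_count_experiment(
    truths: Sequence[SceneTruth],
    array: SensorArray,
    subsets: Sequence[Iterable[int]],
    occlusion_p: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Detection rate (valid fused signal) per active-sensor subset.

    Subsets share common random numbers: the occlusion draw for sensor
    ``s`` in scene ``i`` depends only on ``(seed + i, s)``, so for
    nested subsets detection is monotone scene by scene, isolating the
    effect of sensor count from sampling noise.
    """
    rows = []
    for subset in subsets:
        active = frozenset(subset)
        detected = 0
        for i, truth in enumerate(truths):
            events = simulate_sensor_events(
                truth, array, occlusion_p=occlusion_p,
                active_sensors=active, seed=seed + i,
            )
            if select_signal(events, array) is not None:
                detected += 1
        rows.append(
            {
                "sensors": ",".join(str(s) for s in sorted(active)),
                "n_sensors": len(active),
                "n_scenes": len(truths),
                "detected": detected,
                "detection_rate": detected / len(truths) if truths else float("nan"),
            }
        )
    return pd.DataFrame(rows)
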