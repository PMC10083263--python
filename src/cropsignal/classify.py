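"""Tolerance-zone crop/weed classification and prescription-map rendering.

A circular tolerance zone around the fused label position absorbs the
localization error introduced by trigger/shutter desynchronization: any
plant region that intersects the disc is taken to carry the label and is
classified as crop; every other region is a weed.  When no valid sensor
pair was fused there is no zone and every region is a weed (a missed
detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .vision import PlantComponent

__all__ = [
    "ToleranceZone",
    "ClassificationResult",
    "make_zone",
    "classify_components",
    "render_prescription_map",
]

CROP_COLOR = (255, 0, 0)  # red
WEED_COLOR = (0, 255, 0)  # green


@dataclass(frozen=True)
class ToleranceZone:
    """A disc of radius ``radius_mm`` around the fused label position.

    ``radius_px = radius_mm * px_per_mm`` is kept real-valued; the
    boundary is inclusive (distance <= radius_px counts as inside).
    """

    center: tuple[float, float]  # (x, y)
    radius_mm: float
    radius_px: float


@dataclass(frozen=True)
class ClassificationResult:
    """Per-component crop/weed labels for one scene."""

    components: tuple[PlantComponent, ...]
    labels: tuple[str, ...]  # "crop" | "weed", aligned with components
    zone: ToleranceZone | None

    def __post_init__(self):
        if len(self.components) != len(self.labels):
            raise ValueError("labels must align one-to-one with components")

    @property
    def crop_count(self) -> int:
        return sum(1 for l in self.labels if l == "crop")

    @property
    def weed_count(self) -> int:
        return sum(1 for l in self.labels if l == "weed")

    def by_class(self, label: str) -> list[PlantComponent]:
        return [c for c, l in zip(self.components, self.labels) if l == label]


def make_zone(
    point: tuple[float, float], radius_mm: float, px_per_mm: float
) -> ToleranceZone:
    """Build a tolerance zone from a physical radius and the image scale."""
    if radius_mm <= 0:
        raise DomainError(f"radius_mm must be > 0, got {radius_mm}")
    if px_per_mm <= 0:
        raise DomainError(f"px_per_mm must be > 0, got {px_per_mm}")
    return ToleranceZone(center=tuple(point), radius_mm=radius_mm,
                         radius_px=radius_mm * px_per_mm)


def _min_dist_to_center(comp: PlantComponent, center: tuple[float, float]) -> float:
    dx = comp.pixels[:, 1] - center[0]
    dy = comp.pixels[:, 0] - center[1]
    return float(np.sqrt(np.min(dx * dx + dy * dy)))


def classify_components(
    components: list[PlantComponent],
    zone: ToleranceZone | None,
    *,
    mode: str = "intersect",
) -> ClassificationResult:
    """Assign each component to crop or weed by the tolerance-zone rule.

    In the default ``"intersect"`` mode every component with at least
    one pixel at Euclidean distance <= ``zone.radius_px`` from the zone
    center is crop (boundary inclusive); the rest are weeds.  In
    ``"nearest-centroid"`` mode at most one intersecting component — the
    one whose centroid is nearest the zone center — is crop, for scenes
    where plants crowd the zone.  ``zone=None`` (no valid fused signal)
    classifies everything as weed.
    """
    if mode not in ("intersect", "nearest-centroid"):
        raise DomainError(f"unknown classification mode {mode!r}")
    if zone is None or not components:
        labels = tuple("weed" for _ in components)
        return ClassificationResult(tuple(components), labels, zone)

    hits = [
        _min_dist_to_center(c, zone.center) <= zone.radius_px for c in components
    ]
    if mode == "nearest-centroid" and any(hits):
        cd = [
            np.hypot(c.centroid[0] - zone.center[0], c.centroid[1] - zone.center[1])
            if hit else np.inf
            for c, hit in zip(components, hits)
        ]
        winner = int(np.argmin(cd))
        hits = [i == winner for i in range(len(components))]
    labels = tuple("crop" if h else "weed" for h in hits)
    return ClassificationResult(tuple(components), labels, zone)


def render_prescription_map(
    image: np.ndarray, result: ClassificationResult, *, style: str = "fill"
) -> np.ndarray:
    """Paint crop regions red and weed regions green on a copy of the image.

    ``style="fill"`` paints every region pixel; ``style="contour"``
    paints only the boundary pixels, leaving interiors untouched.
    """
    if style not in ("fill", "contour"):
        raise DomainError(f"unknown render style {style!r}")
    out = np.asarray(image).copy()
    for comp, label in zip(result.components, result.labels):
        color = CROP_COLOR if label == "crop" else WEED_COLOR
        px = comp.pixels if style == "fill" else comp.contour
        out[px[:, 0], px[:, 1]] = color
    return out
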