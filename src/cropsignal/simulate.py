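"""Synthetic conveyor scenes and sensor event streams.

Replaces the physical conveyor rig for testing: each scene is a square
top-view image of one labeled crop plant and 1-6 unlabeled weeds on a
soil background, plus the trigger events the six-sensor array would emit
for the crop's label.  Plant pixels are drawn with HSV colors strictly
inside the segmentation acceptance bands and soil pixels strictly
outside them, so the segmentation contract is satisfiable by
construction and violations indicate pipeline bugs, not render noise.

The label point is placed ON one of the three fusion loci (diagonal,
vertical, anti-diagonal through the image center) and the event stream
is produced by the exact algebraic inverse of the six-case fusion rule,
so fusion round-trips are testable without inventing physical sensor
positions.  An optional jitter displaces the *plants* relative to the
label point, emulating camera-shutter desynchronization; per-sensor
independent dropout emulates occlusion of the label by foliage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import GenerationError, NotInvertibleError
from .fusion import LINE_OF, SensorArray, SensorEvent, line_of
from .vision import HsvThresholds

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "desync_config",
    "generate_scene",
    "generate_truth",
    "invert_fusion",
    "simulate_sensor_events",
    "hsv8_to_rgb",
]


def desync_config() -> "SceneConfig":
    """Scene conditions for the shutter-desynchronization experiment.

    The label position is estimated at trigger time but the image is
    exposed up to two frame periods later; at the conveyor speed of the
    rig (~253 mm/s, 30 ms per frame at 4 px/mm) that displaces the
    plants by up to ~60 px relative to the label point.  Weeds are
    drawn from an annulus around the crop stem, as in a transplant bed
    where weeds crowd the crop.  Under these conditions small tolerance
    radii miss the displaced crop and large radii swallow nearby weeds,
    reproducing the direction of the radius/accuracy trade-off observed
    on the physical system.
    """
    return SceneConfig(
        jitter_px=60.0, weed_placement="around_crop", min_sep_crop_weed=80
    )

_ALL_SENSORS = frozenset((1, 2, 3, 4, 5, 6))
#: Low-id representative sensor of each detection line.
_LINE_SENSOR = {"A": 1, "B": 2, "C": 3}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene generator.

    Color ranges are HSV triples (hue on 0..179) kept at least two
    counts inside (plants) or outside (soil) the default segmentation
    bands, so the 8-bit HSV->RGB->HSV round-trip cannot cross a
    threshold.  Geometry defaults give one crop canopy (a cluster of
    2-5 overlapping ellipses around the stem) roughly 60-110 px across
    and weeds 16-44 px across in a 720 px frame, with separations wide
    enough that a 12.5 mm tolerance disc at default scale (4 px/mm)
    never reaches a weed: the error-free regime.  ``jitter_px`` shifts
    the plants relative to the label point (shutter desync); 0 disables.
    """

    image_size: int = 720
    n_weeds: tuple[int, int] = (1, 6)
    crop_radius: tuple[int, int] = (18, 40)  # per-ellipse semi-axis range, px
    crop_ellipses: tuple[int, int] = (2, 5)
    weed_radius: tuple[int, int] = (8, 22)
    plant_hue: tuple[int, int] = (35, 75)
    plant_sat: tuple[int, int] = (130, 230)
    plant_val: tuple[int, int] = (100, 220)
    soil_hue: tuple[int, int] = (2, 7)
    soil_sat: tuple[int, int] = (40, 140)
    soil_val: tuple[int, int] = (50, 150)
    jitter_px: float = 0.0
    px_per_mm: float = 4.0
    min_sep_crop_weed: int = 150
    min_sep_weed_weed: int = 60
    #: "uniform" scatters weeds over the frame; "around_crop" draws them
    #: area-uniformly from an annulus around the crop stem, emulating a
    #: bed where weeds crowd the transplant.
    weed_placement: str = "uniform"
    around_radius: tuple[int, int] = (80, 250)
    locus_offset: tuple[int, int] = (0, 250)  # d range for label placement, px
    max_retries: int = 100

    def __post_init__(self):
        thr = HsvThresholds()
        if not (thr.h_low < self.plant_hue[0] and self.plant_hue[1] < thr.h_high):
            raise ValueError("plant hue range must lie inside the acceptance band")
        if self.soil_hue[1] >= thr.h_low - 1:
            raise ValueError("soil hue range must clear the low hue threshold")
        if not (1 <= self.n_weeds[0] <= self.n_weeds[1] <= 6):
            raise ValueError("n_weeds range must sit within 1..6")
        if self.weed_placement not in ("uniform", "around_crop"):
            raise ValueError(
                f"weed_placement must be 'uniform' or 'around_crop', "
                f"got {self.weed_placement!r}"
            )


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one synthetic scene.

    ``label_point`` is the on-locus point encoded in the sensor events;
    ``crop_centroid`` is the actual crop blob centroid, which departs
    from the label point by the stem offset plus jitter.  ``crop_mask``
    / ``weed_masks`` are per-plant boolean rasters (``None`` when the
    scene was generated truth-only).
    """

    label_point: tuple[int, int]
    crop_centroid: tuple[float, float]
    weed_centroids: tuple[tuple[float, float], ...]
    crop_mask: np.ndarray | None = None
    weed_masks: tuple[np.ndarray, ...] = ()

    @property
    def n_weeds(self) -> int:
        return len(self.weed_centroids)


def invert_fusion(
    point: tuple[int, int], array: SensorArray
) -> tuple[int, int, float]:
    """Exact algebraic inverse of the six-case fusion rule.

    Maps an on-locus point back to a trigger pair and time gap such
    that fusing ``(ser_1, ser_2, dt)`` reproduces the point exactly.
    Locus -> case: diagonal ``(a, a)``, ``a <= c`` -> (line A, line B),
    ``d = c - a``; vertical ``(c, y)`` -> (B, A) with ``d = y - c`` when
    ``y > c``, else (B, C) with ``d = c - y``; anti-diagonal
    ``(c - k, c + k)`` -> (C, B), ``d = k``.  The low-id sensor of each
    line represents it.  Off-locus points raise
    :class:`~cropsignal.errors.NotInvertibleError`.
    """
    x, y = point
    c = array.center
    if array.mirror:
        x, y = y, x
    if x == c:  # vertical locus (includes the center)
        if y > c:
            la, lb, d = "B", "A", y - c
        else:
            la, lb, d = "B", "C", c - y
    elif x == y and x < c:  # main diagonal
        la, lb, d = "A", "B", c - x
    elif x + y == 2 * c and x < c:  # anti-diagonal
        la, lb, d = "C", "B", c - x
    else:
        raise NotInvertibleError(f"point {point} lies on no fusion locus")
    return _LINE_SENSOR[la], _LINE_SENSOR[lb], d / array.speed_px_s


def simulate_sensor_events(
    truth: SceneTruth,
    array: SensorArray,
    occlusion_p: float = 0.0,
    active_sensors: frozenset[int] | set[int] = _ALL_SENSORS,
    seed: int = 0,
) -> list[SensorEvent]:
    """Emit the trigger events the sensor rig would produce for a scene.

    The ideal ordered pair and gap come from :func:`invert_fusion` on
    the (un-jittered) label point; both sensors of the first line fire
    at ``t = 0`` and both sensors of the second line at ``t = dt``.
    Each active sensor's event is then independently dropped with
    probability ``occlusion_p`` (foliage occlusion); sensors outside
    ``active_sensors`` never fire.  Occlusion draws are indexed by
    sensor id only, so nested sensor subsets see common random numbers.
    """
    if not 0 <= occlusion_p <= 1:
        raise ValueError(f"occlusion_p must be in [0, 1], got {occlusion_p}")
    if not active_sensors:
        raise ValueError("active_sensors must be non-empty")
    ser_1, ser_2, dt = invert_fusion(truth.label_point, array)
    t_of_line = {line_of(ser_1): 0.0, line_of(ser_2): dt}
    rng = np.random.default_rng(seed)
    survive = {s: rng.random() >= occlusion_p for s in sorted(_ALL_SENSORS)}
    events = [
        SensorEvent(sensor_id=s, timestamp=t_of_line[LINE_OF[s]])
        for s in sorted(_ALL_SENSORS)
        if LINE_OF[s] in t_of_line and s in active_sensors and survive[s]
    ]
    return sorted(events, key=lambda e: (e.timestamp, e.sensor_id))


def _sample_label_point(rng: np.random.Generator, config: SceneConfig,
                        array: SensorArray) -> tuple[int, int]:
    c = array.center
    d = int(rng.integers(config.locus_offset[0], config.locus_offset[1] + 1))
    locus = rng.integers(0, 3)
    if locus == 0:  # main diagonal, case (A, B)
        return (c - d, c - d)
    if locus == 1:  # vertical line, case (B, A) or (B, C)
        return (c, c + d) if rng.random() < 0.5 else (c, c - d)
    return (c - d, c + d)  # anti-diagonal, case (C, B)


def _paint_ellipse(mask: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                   theta: float) -> None:
    size = mask.shape[0]
    r_ext = int(np.ceil(max(rx, ry))) + 1
    r0, r1 = max(0, int(cy) - r_ext), min(size, int(cy) + r_ext + 1)
    c0, c1 = max(0, int(cx) - r_ext), min(size, int(cx) + r_ext + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    mask[r0:r1, c0:c1] |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _crop_mask(rng: np.random.Generator, config: SceneConfig,
               stem: tuple[float, float]) -> np.ndarray:
    """Canopy = central ellipse at the stem plus 1-4 offset 'leaves'."""
    mask = np.zeros((config.image_size, config.image_size), dtype=bool)
    lo, hi = config.crop_radius
    n = int(rng.integers(config.crop_ellipses[0], config.crop_ellipses[1] + 1))
    # Central ellipse guarantees the stem (label attachment) is plant pixel.
    _paint_ellipse(mask, stem[0], stem[1], rng.uniform(lo, hi), rng.uniform(lo, hi),
                   rng.uniform(0, np.pi))
    for _ in range(n - 1):
        ang, off = rng.uniform(0, 2 * np.pi), rng.uniform(0.3, 0.8) * lo
        _paint_ellipse(
            mask,
            stem[0] + off * np.cos(ang),
            stem[1] + off * np.sin(ang),
            rng.uniform(lo, hi),
            rng.uniform(lo, hi),
            rng.uniform(0, np.pi),
        )
    return mask


def hsv8_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion: 8-bit HSV (hue 0..179) to 8-bit RGB."""
    h = hsv[..., 0].astype(np.float64) * 2.0  # degrees
    s = hsv[..., 1].astype(np.float64) / 255.0
    v = hsv[..., 2].astype(np.float64)
    hp = (h / 60.0) % 6.0
    i = np.floor(hp).astype(int)
    f = hp - i
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.floor(np.stack([r, g, b], axis=-1) + 0.5).astype(np.uint8)


def generate_truth(
    config: SceneConfig, seed: int, array: SensorArray | None = None
) -> SceneTruth:
    """Sample a scene layout (label point + plant centers) without rendering.

    Sufficient for sensor-level experiments where the image itself is
    never segmented.  Deterministic given ``(config, seed)`` and
    consistent with :func:`generate_scene` at the layout level.
    """
    if array is None:
        array = SensorArray(center=config.image_size // 2,
                            image_size=config.image_size)
    rng = np.random.default_rng(seed)
    label = _sample_label_point(rng, config, array)
    if config.jitter_px > 0:
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0, config.jitter_px)
        stem = (label[0] + r * np.cos(ang), label[1] + r * np.sin(ang))
    else:
        stem = (float(label[0]), float(label[1]))

    k = int(rng.integers(config.n_weeds[0], config.n_weeds[1] + 1))
    margin = config.weed_radius[1] + 4
    centers: list[tuple[float, float]] = []
    for _ in range(k):
        for attempt in range(config.max_retries + 1):
            if attempt == config.max_retries:
                raise GenerationError(
                    f"could not place weed {len(centers) + 1} after "
                    f"{config.max_retries} retries; loosen separations"
                )
            if config.weed_placement == "around_crop":
                lo, hi = config.around_radius
                u = np.sqrt(rng.uniform(lo * lo, hi * hi))  # area-uniform annulus
                ang = rng.uniform(0, 2 * np.pi)
                cx = stem[0] + u * np.cos(ang)
                cy = stem[1] + u * np.sin(ang)
                if not (margin <= cx < config.image_size - margin
                        and margin <= cy < config.image_size - margin):
                    continue
            else:
                cx = rng.uniform(margin, config.image_size - margin)
                cy = rng.uniform(margin, config.image_size - margin)
            if np.hypot(cx - stem[0], cy - stem[1]) < config.min_sep_crop_weed:
                continue
            if any(np.hypot(cx - ox, cy - oy) < config.min_sep_weed_weed
                   for ox, oy in centers):
                continue
            centers.append((cx, cy))
            break
    return SceneTruth(
        label_point=label,
        crop_centroid=stem,  # refined to the blob centroid when rendering
        weed_centroids=tuple(centers),
    )


def generate_scene(
    config: SceneConfig, seed: int, array: SensorArray | None = None
) -> tuple[np.ndarray, SceneTruth]:
    """Render one synthetic scene: an RGB image and its ground truth.

    Deterministic given ``(config, seed)``.  Soil pixels get per-pixel
    noise drawn from the soil HSV ranges (all outside the acceptance
    bands); plant pixels from the plant ranges (all inside).  The truth
    carries per-plant masks and the rendered crop blob centroid.
    """
    layout = generate_truth(config, seed, array)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CE2E]))
    size = config.image_size

    crop = _crop_mask(rng, config, layout.crop_centroid)
    weed_masks = []
    for cx, cy in layout.weed_centroids:
        m = np.zeros((size, size), dtype=bool)
        lo, hi = config.weed_radius
        _paint_ellipse(m, cx, cy, rng.uniform(lo, hi), rng.uniform(lo, hi),
                       rng.uniform(0, np.pi))
        weed_masks.append(m)

    hsv = np.empty((size, size, 3), dtype=np.uint8)
    for ch, band in enumerate((config.soil_hue, config.soil_sat, config.soil_val)):
        hsv[..., ch] = rng.integers(band[0], band[1] + 1, size=(size, size))
    plant = crop.copy()
    for m in weed_masks:
        plant |= m
    n_plant = int(plant.sum())
    for ch, band in enumerate((config.plant_hue, config.plant_sat, config.plant_val)):
        hsv[..., ch][plant] = rng.integers(band[0], band[1] + 1, size=n_plant)

    rr, cc = np.nonzero(crop)
    truth = replace(
        layout,
        crop_centroid=(float(cc.mean()), float(rr.mean())),
        crop_mask=crop,
        weed_masks=tuple(weed_masks),
    )
    return hsv8_to_rgb(hsv), truth


def dump_truth(truth: SceneTruth, path: str | Path) -> None:
    """Persist a scene truth as JSON (centroids + per-plant bounding boxes)."""

    def bbox(mask):
        rr, cc = np.nonzero(mask)
        return [int(rr.min()), int(cc.min()), int(rr.max()), int(cc.max())]

    payload = {
        "label_point": list(truth.label_point),
        "crop_centroid": list(truth.crop_centroid),
        "weed_centroids": [list(c) for c in truth.weed_centroids],
        "crop_bbox": bbox(truth.crop_mask) if truth.crop_mask is not None else None,
        "weed_bboxes": [bbox(m) for m in truth.weed_masks],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path: str | Path) -> SceneTruth:
    """Load a truth JSON written by :func:`dump_truth` (masks not restored)."""
    raw = json.loads(Path(path).read_text())
    return SceneTruth(
        label_point=tuple(raw["label_point"]),
        crop_centroid=tuple(raw["crop_centroid"]),
        weed_centroids=tuple(tuple(c) for c in raw["weed_centroids"]),
    )
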