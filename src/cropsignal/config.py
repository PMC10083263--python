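"""Flat key-value JSON run configuration.

One config dialect covers the whole pipeline: sensor geometry and
conveyor speed, HSV thresholds, tolerance radius and image scale, and
the synthetic-scene parameters.  Unknown keys are rejected by name so a
typo never silently falls back to a default.  A run is reproducible
from its persisted config plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .fusion import SensorArray
from .simulate import SceneConfig
from .vision import HsvThresholds

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # sensor array
    center: int = 360
    image_size: int = 720
    speed_px_s: float = 400.0
    mirror: bool = False
    # segmentation thresholds
    h_low: int = 10
    h_high: int = 120
    s_low: int = 10
    s_high: int = 255
    v_low: int = 10
    v_high: int = 255
    # classification
    radius_mm: float = 7.5
    px_per_mm: float = 4.0
    classify_mode: str = "intersect"
    render_style: str = "fill"
    match_radius_px: float = 60.0
    # scene generation
    n_weeds_min: int = 1
    n_weeds_max: int = 6
    weed_placement: str = "uniform"
    min_sep_crop_weed: int = 150
    jitter_px: float = 0.0
    occlusion_p: float = 0.0
    seed: int = 0

    def sensor_array(self) -> SensorArray:
        return SensorArray(center=self.center, speed_px_s=self.speed_px_s,
                           image_size=self.image_size, mirror=self.mirror)

    def thresholds(self) -> HsvThresholds:
        return HsvThresholds(
            h_low=self.h_low, h_high=self.h_high, s_low=self.s_low,
            s_high=self.s_high, v_low=self.v_low, v_high=self.v_high,
        )

    def scene_config(self) -> SceneConfig:
        return SceneConfig(
            image_size=self.image_size,
            n_weeds=(self.n_weeds_min, self.n_weeds_max),
            weed_placement=self.weed_placement,
            min_sep_crop_weed=self.min_sep_crop_weed,
            jitter_px=self.jitter_px,
            px_per_mm=self.px_per_mm,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ConfigError(key, "unknown key")
        cfg = cls(**raw)
        _validate(cfg)
        return cfg


def _validate(cfg: RunConfig) -> None:
    if cfg.speed_px_s <= 0:
        raise ConfigError("speed_px_s", "must be > 0")
    if cfg.image_size != 2 * cfg.center:
        raise ConfigError("image_size", f"must equal 2 * center ({2 * cfg.center})")
    if cfg.radius_mm <= 0:
        raise ConfigError("radius_mm", "must be > 0")
    if cfg.px_per_mm <= 0:
        raise ConfigError("px_per_mm", "must be > 0")
    if not 0 <= cfg.occlusion_p <= 1:
        raise ConfigError("occlusion_p", "must be in [0, 1]")
    if not 1 <= cfg.n_weeds_min <= cfg.n_weeds_max <= 6:
        raise ConfigError("n_weeds_min", "weed count range must sit within 1..6")
    for name in ("h", "s", "v"):
        if getattr(cfg, f"{name}_low") > getattr(cfg, f"{name}_high"):
            raise ConfigError(f"{name}_low", f"must be <= {name}_high")
    if cfg.weed_placement not in ("uniform", "around_crop"):
        raise ConfigError("weed_placement", "must be 'uniform' or 'around_crop'")
    if cfg.classify_mode not in ("intersect", "nearest-centroid"):
        raise ConfigError("classify_mode", "must be 'intersect' or 'nearest-centroid'")
    if cfg.render_style not in ("fill", "contour"):
        raise ConfigError("render_style", "must be 'fill' or 'contour'")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a config file, or the defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError("<file>", f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("<file>", "config must be a JSON object")
    try:
        return RunConfig.from_mapping(raw)
    except TypeError as exc:
        raise ConfigError("<file>", str(exc)) from exc
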