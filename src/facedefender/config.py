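"""Run configuration: defaults, YAML overrides and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["FusionConfig", "QualityThresholds", "RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FusionConfig:
    """Parameters of the eye-transplant fusion step.

    constraint
        ``"similarity"`` (default) restricts the per-eye transform to a
        uniform scale plus rotation, preserving the proportions of the
        transplanted region; ``"general"`` allows a full affine map.
    roi_margin
        Outward dilation of the periocular convex hull, pixels.
    feather_sigma
        Gaussian sigma of the mask feathering, pixels.  With the default
        margin of 8 px and sigma 6 px the soft edge stays close to the
        dilated hull.
    skin_ring_width
        Width of the avatar skin annulus just outside the ROI whose
        channel statistics are the color-transfer target, pixels.
    canvas_side
        Side of the canonical square canvas, pixels.
    """

    constraint: str = "similarity"
    roi_margin: float = 8.0
    feather_sigma: float = 6.0
    skin_ring_width: float = 15.0
    canvas_side: int = 1024

    def __post_init__(self):
        if self.constraint not in ("similarity", "general"):
            raise ConfigError("constraint must be 'similarity' or 'general'")
        if self.roi_margin <= 0 or self.feather_sigma <= 0 or self.skin_ring_width <= 0:
            raise ConfigError("margins and sigma must be positive")
        if self.canvas_side <= 0:
            raise ConfigError("canvas_side must be positive")


@dataclass(frozen=True)
class QualityThresholds:
    """Pose thresholds for the poor-quality image gate."""

    roll_max_deg: float = 5.0
    yaw_ratio_low: float = 0.8
    yaw_ratio_high: float = 1.25


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration: defaults ← YAML file ← flags.

    ``z_policy`` selects the standard-normal critical value used by the
    sample-size formulas: ``"rounded"`` uses the conventional two-decimal
    value (1.96 at the 0.95 level), ``"exact"`` the exact quantile.
    ``laterality`` controls whether diagnostic outputs label eyes by the
    subject's anatomy (default) or by image side.
    """

    fusion: FusionConfig = field(default_factory=FusionConfig)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    level: float = 0.95
    interval_mode: str = "reference_range"
    bootstrap_B: int = 2000
    iqr_k: float = 1.5
    z_policy: str = "rounded"
    laterality: str = "anatomical"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ConfigError("level must be in (0, 1)")
        if self.interval_mode not in ("reference_range", "ci_mean"):
            raise ConfigError("interval_mode must be 'reference_range' or 'ci_mean'")
        if self.z_policy not in ("rounded", "exact"):
            raise ConfigError("z_policy must be 'rounded' or 'exact'")
        if self.laterality not in ("anatomical", "image"):
            raise ConfigError("laterality must be 'anatomical' or 'image'")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} must contain a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        fusion_kw = data.pop("fusion", {})
        quality_kw = data.pop("quality", {})
        try:
            return cls(
                fusion=FusionConfig(**fusion_kw),
                quality=QualityThresholds(**quality_kw),
                **data,
            )
        except TypeError as exc:
            raise ConfigError(f"unknown configuration key: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration, logged with outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
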