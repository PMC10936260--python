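"""Pipeline configuration: schema-validated parameters with defaults.

Every threshold of the analysis is configurable here; the defaults are the
constants of the kicking feature definitions (60-s segments, 50 ms / 11.5
degrees kick-cycle rules, 5-degrees-per-1-s DOF rest rule, 0.9 outlier
bound, alpha = 0.05).  Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessConfig(_Strict):
    median_window: int = Field(5, ge=3)
    activity_threshold_deg_s: float = Field(10.0, gt=0)
    activity_smooth_s: float = Field(0.1, ge=0)
    activity_min_event_s: float = Field(0.1, ge=0)
    activity_merge_gap_s: float = Field(0.1, ge=0)
    gravity_corrected_accel: bool = True


class PhaseConfig(_Strict):
    rest_deg: float = Field(5.0, gt=0)
    rest_window_s: float = Field(1.0, gt=0)


class KickCycleConfig(_Strict):
    min_flex_ms: float = Field(50.0, gt=0)
    min_excursion_deg: float = Field(11.5, gt=0)


class SegmentationConfig(_Strict):
    segment_seconds: float = Field(60.0, gt=0)


class OutlierConfig(_Strict):
    max_fraction: float = Field(0.9, gt=0, le=1)


class ModelConfig(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    quad_delta_r2: float = Field(0.05, ge=0)
    grid_step_weeks: float = Field(0.1, gt=0)


class PipelineConfig(_Strict):
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    phase: PhaseConfig = Field(default_factory=PhaseConfig)
    kick_cycle: KickCycleConfig = Field(default_factory=KickCycleConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    outlier: OutlierConfig = Field(default_factory=OutlierConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class ConfigError(ValueError):
    """Raised when a config file fails schema validation."""


def load_config(path=None) -> PipelineConfig:
    """Load a YAML pipeline config; ``None`` yields all defaults."""
    if path is None:
        return PipelineConfig()
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
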