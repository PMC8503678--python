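"""Validated pipeline configuration (YAML or JSON on disk).

Defaults carry the operating constants of the screening method: the
60000-pixel area filter, the 30% fill-ratio filter, and the 0.426
high-specificity classification threshold.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .detection import MIN_AREA_PX, MIN_FILL_RATIO
from .scoring import (DEFAULT_MIN_INSIDE_FRACTION, DEFAULT_TILE_SIZE,
                      THRESHOLD_HIGH_SPECIFICITY)


class DetectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    binarization: str = "otsu"
    fixed_threshold: float | None = Field(default=None, ge=0.0, le=1.0)
    closing_radius_px: int = Field(default=5, ge=0)
    min_area_px: int = Field(default=MIN_AREA_PX, ge=0)
    min_fill_ratio: float = Field(default=MIN_FILL_RATIO, ge=0.0, le=1.0)
    rect_mode: str = "rotated"

    @model_validator(mode="after")
    def _check(self) -> "DetectionSettings":
        if self.binarization not in ("otsu", "fixed"):
            raise ValueError("binarization must be 'otsu' or 'fixed'")
        if self.binarization == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed binarization requires fixed_threshold")
        if self.rect_mode not in ("rotated", "axis"):
            raise ValueError("rect_mode must be 'rotated' or 'axis'")
        return self


class ScoringSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tile_size_px: int = Field(default=DEFAULT_TILE_SIZE, gt=0)
    min_inside_fraction: float = Field(default=DEFAULT_MIN_INSIDE_FRACTION,
                                       ge=0.0, le=1.0)
    threshold: float = Field(default=THRESHOLD_HIGH_SPECIFICITY,
                             ge=0.0, le=1.0)
    model_path: str | None = None


class GeneratorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    width_px: int = Field(default=1600, gt=0)
    height_px: int = Field(default=1200, gt=0)
    background_rgb: tuple[int, int, int] = (236, 230, 233)
    background_noise_sd: float = Field(default=3.0, ge=0.0)
    n_hematopoietic: int = Field(default=150, ge=0)
    hematopoietic_radius_px: tuple[float, float] = (4.0, 9.0)
    n_cancer_clusters: int = Field(default=3, ge=0)
    cells_per_cluster: tuple[int, int] = (20, 80)
    cancer_cell_radius_px: tuple[float, float] = (24.0, 40.0)
    cluster_cohesion: float = Field(default=0.6, ge=0.0, le=1.0)
    n_rbc_clumps: int = Field(default=3, ge=0)
    n_artifacts: int = Field(default=4, ge=0)
    target_cluster_area_px: tuple[int, int] = (80_000, 120_000)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    detection: DetectionSettings = Field(default_factory=DetectionSettings)
    scoring: ScoringSettings = Field(default_factory=ScoringSettings)
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; an empty file yields defaults."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return PipelineConfig.model_validate(payload)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
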