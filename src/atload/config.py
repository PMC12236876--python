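"""Run configuration: one validated, hashable object for a whole analysis."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .cumulative_load import LoadThresholds
from .signal_qc import ErroneousRules
from .tendon_load import SensorGeometry

__all__ = ["RunConfig", "CohortConfig", "GeometryConfig", "QCConfig", "ThresholdConfig"]


class CohortConfig(BaseModel):
    n_participants: int = Field(default=15, ge=1)
    n_days: int = Field(default=10, ge=1)
    volume_min: float = Field(default=0.0, ge=0.0, le=1.0)
    volume_max: float = Field(default=1.0, ge=0.0, le=1.0)
    noise_scale: float = Field(default=1.0, ge=0.0)
    day_scale: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check_range(self) -> "CohortConfig":
        if self.volume_max < self.volume_min:
            raise ValueError("volume_max must be >= volume_min")
        return self


class GeometryConfig(BaseModel):
    r_heel: float = -0.06
    r_mid: float = 0.04
    r_fore: float = 0.11
    r_at: float = Field(default=0.05, gt=0)
    size_factor: float = Field(default=1.0, gt=0)

    def to_geometry(self) -> SensorGeometry:
        return SensorGeometry(
            r_heel=self.r_heel, r_mid=self.r_mid, r_fore=self.r_fore, r_at=self.r_at
        ).scaled(self.size_factor)


class QCConfig(BaseModel):
    window_s: float = Field(default=30.0, gt=0)
    tolerance_bw: float = Field(default=0.02, ge=0)
    # median daily loading hours below which a participant is excluded;
    # 1.0 keeps full-day wearers with ~2-3 h daily loading while dropping
    # token (1-3 h recording) wear
    adherence_min_h: float = Field(default=1.0, ge=0)
    loaded_frac: float = Field(default=0.95, gt=0, le=1)
    min_unloaded_gap_s: float = Field(default=2.0, ge=0)
    neg_thresh_bw: float = Field(default=0.05, ge=0)
    neg_frac: float = Field(default=0.01, ge=0, le=1)
    min_duration_s: float = Field(default=60.0, ge=0)

    def to_rules(self) -> ErroneousRules:
        return ErroneousRules(
            loaded_frac=self.loaded_frac,
            min_unloaded_gap_s=self.min_unloaded_gap_s,
            neg_thresh_bw=self.neg_thresh_bw,
            neg_frac=self.neg_frac,
            min_duration_s=self.min_duration_s,
        )


class ThresholdConfig(BaseModel):
    overall: float = Field(default=0.3, gt=0)
    high: float = Field(default=3.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdConfig":
        if self.high <= self.overall:
            raise ValueError("high threshold must exceed overall threshold")
        return self

    def to_thresholds(self) -> LoadThresholds:
        return LoadThresholds(overall=self.overall, high=self.high)


class RunConfig(BaseModel):
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    output_dir: str = "atload_run"
    cohort: CohortConfig = CohortConfig()
    geometry: GeometryConfig = GeometryConfig()
    qc: QCConfig = QCConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    alpha: float = Field(default=0.05, gt=0, lt=1)
    sample_rate_hz: float = Field(default=20.0, gt=0)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True, default_flow_style=False)
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
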