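"""Pipeline configuration: one validated document tying every stage together.

Unknown keys are rejected (typos in threshold names should fail loudly, not
silently fall back to defaults).  Configs load from JSON or YAML; YAML needs
pyyaml, which is optional.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .detect_stats import DetectionThresholds
from .pipeline import MetricParams
from .synthgen import ScenarioConfig, default_protocol
from .track_extract import ROI

__all__ = ["ROISpec", "MetricConfig", "DetectionConfig", "PipelineConfig"]


class ROISpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    row: int = Field(ge=0)
    col: int = Field(ge=0)
    half_rows: int = Field(default=15, ge=0)
    half_cols: int = Field(default=15, ge=0)

    def to_roi(self) -> ROI:
        return ROI(center=(self.row, self.col), half_size=(self.half_rows, self.half_cols))


class MetricConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_detect: float = Field(default=3.0, gt=0)
    m_consec: int = Field(default=3, ge=1)
    pre_window: float = Field(default=10.0, gt=0)
    eps_abs: float = Field(default=1e-6, gt=0)

    def to_params(self) -> MetricParams:
        return MetricParams(**self.model_dump())


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    theta_dec: float = Field(default=0.7, gt=0, lt=1)
    detect_frac_min: float = Field(default=0.5, ge=0, le=1)

    def to_thresholds(self) -> DetectionThresholds:
        return DetectionThresholds(**self.model_dump())


def _default_rois() -> dict[str, ROISpec]:
    return {
        "central": ROISpec(row=64, col=64),
        "peripheral": ROISpec(row=92, col=92),
    }


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scenario: ScenarioConfig = Field(default_factory=default_protocol)
    rois: dict[str, ROISpec] = Field(default_factory=_default_rois)
    search_radius: int = Field(default=8, ge=1)
    metrics: MetricConfig = Field(default_factory=MetricConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    seed: int | None = None  # overrides scenario.seed when given
    log_level: str = "INFO"

    def effective_scenario(self) -> ScenarioConfig:
        if self.seed is None:
            return self.scenario
        return self.scenario.model_copy(update={"seed": self.seed})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)
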