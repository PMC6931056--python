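"""Run configuration: a single YAML-serializable object covering I/O,
detection and segmentation settings, validated strictly (unknown keys are
rejected so typos cannot silently fall back to defaults)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from .detect import DetectionConfig
from .errors import ConfigurationError
from .io import IOConfig

__all__ = ["DetectionSettings", "RunConfig"]


class DetectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    threshold_av: float = -90.0
    swing_min_amp: float = 50.0
    search_window: float = 0.40
    refractory: float = 0.40
    smoothing_cutoff: float = 15.0

    def to_detection_config(self) -> DetectionConfig:
        return DetectionConfig(**self.model_dump()).validate()


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    axis: str = "y"
    sign: int = 1
    sample_rate: float | None = None
    detection: DetectionSettings = DetectionSettings()
    gap_limit: float = 10.0
    seed: int = 0

    def to_io_config(self) -> IOConfig:
        return IOConfig(sample_rate=self.sample_rate, axis=self.axis, sign=self.sign)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls.model_validate(data)
        except (yaml.YAMLError, PydanticValidationError) as exc:
            raise ConfigurationError(f"invalid config file {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
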