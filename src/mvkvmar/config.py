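"""Pipeline configuration schema (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulatorConfig(_Strict):
    phantom: str = "paper-default"  # or path to a phantom fixture (unused here)
    grid_size: int = 256
    pixel_spacing_mm: float = 1.18
    views: int = 180
    kv_photons_per_bin: float = 1e5
    mv_photons_per_bin: float = 8e3
    mv_detector_blur_mm: float = 1.5
    seed: int = 0


class CalibrationConfig(_Strict):
    curve_csv: str | None = None  # None -> "fit-from-simulation"
    n_rods: int = 5


class FusionConfig(_Strict):
    threshold_hu: float = 3000.0
    r_lo: float = 0.05
    r_hi: float = 0.40
    sigma_mm: float = 60.0
    fill_hu: float = 0.0

    @model_validator(mode="after")
    def _check_ramp(self) -> "FusionConfig":
        if not (0 <= self.r_lo < self.r_hi):
            raise ValueError("fusion: need 0 <= r_lo < r_hi")
        return self


class MarConfig(_Strict):
    method: str = "fusion"  # fusion | limar | nmar | nmar-mv
    filter_name: str = "ramp"
    trace_epsilon_cm: float | None = None
    do_register: bool = False

    @model_validator(mode="after")
    def _check_method(self) -> "MarConfig":
        if self.method not in ("fusion", "limar", "nmar", "nmar-mv"):
            raise ValueError(f"unknown MAR method {self.method!r}")
        return self


class EvaluationConfig(_Strict):
    band_width_mm: float = 10.0
    metal_margin_mm: float = 2.0


class PipelineConfig(_Strict):
    simulator: SimulatorConfig = SimulatorConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    fusion: FusionConfig = FusionConfig()
    mar: MarConfig = MarConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)
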