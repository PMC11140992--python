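"""Declarative pipeline configuration with schema validation.

Every stage parameter lives in one validated document (YAML on disk);
unknown keys are rejected so typos fail loudly.  The manifest written by
the pipeline records the config hash and seed, making every run
reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    rows: int = 320
    cols: int = 512
    axial_px_um: float = 1.6
    lateral_px_um: float = 2.8
    onh_col: int | None = None
    frame_range: tuple[int, int] | None = None   # 1-based inclusive, e.g. [450, 549]


class RegistrationConfig(_Strict):
    rot_max_deg: float = 3.0
    rot_step_deg: float = 0.1
    shift_max_px: float = 10.0
    window: int = 10
    n_iter: int = 3
    ncc_floor: float = 0.6
    reference_index: int = 0


class SegmentationConfig(_Strict):
    band: int = 12
    max_jump: int = 2
    smooth_sigma: float = 1.5
    peak_band: int = 6


class RoiConfig(_Strict):
    inner_um: float = 350.0
    outer_um: float = 624.0

    @model_validator(mode="after")
    def _check(self):
        if self.inner_um >= self.outer_um:
            raise ValueError("inner_um must be < outer_um")
        return self


class MeasurementConfig(_Strict):
    intensity_scale: float = 65535.0 / 256.0
    baseline_mode: str = "chord"


class StatsConfig(_Strict):
    alpha: float = 0.05
    collapse_sides: bool = True


class GroupConfig(_Strict):
    label: str
    condition: str = "light"
    n_mice: int = 5
    elm_rpe_um: float = 50.0
    ez_elongation: float = 1.0
    cs_mean: float = 15.0
    cs_shape: float = 30.0
    acuity_mean: float = 0.39
    acuity_sd: float = 0.015
    elm_rpe_sd: float = 0.8


class SimulateConfig(_Strict):
    groups: list[GroupConfig]
    n_frames: int = 5
    speckle_sigma: float = 0.05
    curvature_um: float = 15.0
    max_jitter_rot_deg: float = 0.5
    max_jitter_shift_px: float = 2.0


class PipelineConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    registration: RegistrationConfig = Field(default_factory=RegistrationConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    roi: RoiConfig = Field(default_factory=RoiConfig)
    measurement: MeasurementConfig = Field(default_factory=MeasurementConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    simulate: SimulateConfig | None = None
    seed: int = 0
    out_dir: str = "octenergy_out"
    write_intermediates: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))
        return path

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
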