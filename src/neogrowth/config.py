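"""Run configuration: a validated schema binding geometry, growth
parameters and output options into one reproducible run description.

Configs are plain YAML mappings; every default is recorded explicitly in
the output metadata so a run can be reproduced from its sidecar alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class ChannelGeometryConfig(BaseModel):
    kind: Literal["channel"] = "channel"
    shape: Literal["triangle", "square", "hexagon", "circle"]
    d: float = Field(gt=0, description="size parameter, mm")
    height: float = 2.0


class GyroidGeometryConfig(BaseModel):
    kind: Literal["gyroid"] = "gyroid"
    period: Optional[float] = Field(default=None, gt=0)
    pore_size: Optional[float] = Field(default=None, gt=0)
    wall_thickness: float = Field(gt=0)
    n_cells: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _one_size(self):
        if (self.period is None) == (self.pore_size is None):
            raise ValueError("give exactly one of period or pore_size")
        return self


class ParamsConfig(BaseModel):
    A: float = Field(ge=0, description="growth coefficient, mm²/day")
    eps: float = Field(default=1e-4, ge=0)
    max_step_frac: float = Field(default=0.5, gt=0, le=1)
    redistance_every: int = Field(default=5, ge=1)
    kappa_cap: Optional[float] = None
    layer: float = Field(default=0.010, ge=0, description="initial film, mm")


class OutputConfig(BaseModel):
    directory: str = "out"
    record_at: list[float] = Field(default_factory=lambda: [10.0, 21.0])
    t_end: float = Field(default=21.0, gt=0)
    snapshots: bool = False


class RunConfig(BaseModel):
    geometry: ChannelGeometryConfig | GyroidGeometryConfig
    params: ParamsConfig
    output: OutputConfig = OutputConfig()
    spacing: Optional[float] = Field(default=None, gt=0)
    voxel_budget: int = Field(default=2_000_000, gt=0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)
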