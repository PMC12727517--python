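"""Validated run configuration (YAML) and bundle loading."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io
from .core import ValidationError, WorldData
from .energetics import AllometricModel, AllometricParams
from .uncertainty import MonteCarloConfig


class AllometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: float
    b: float
    residual_se_log10: float = 0.15


class AllometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mammal: AllometryBlock = AllometryBlock(a=4.82, b=0.734)
    bird: AllometryBlock = AllometryBlock(a=10.5, b=0.681)

    def to_model(self) -> AllometricModel:
        return AllometricModel(
            mammal=AllometricParams(self.mammal.a, self.mammal.b, self.mammal.residual_se_log10),
            bird=AllometricParams(self.bird.a, self.bird.b, self.bird.residual_se_log10),
        )


class MonteCarloBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sims: int = 10_000
    seed: int = 0
    variance_split: float = Field(0.5, ge=0.0, le=1.0)
    mass_sd_fraction: float = 0.15
    mass_lower_bound_g: float = 1.0
    dee_se_log10: float | None = None
    intactness_upper_bound: float = 2.0
    diet_halfwidth: float = 0.1
    chunk_size: int = 500

    def to_config(self, **overrides) -> MonteCarloConfig:
        payload = self.model_dump()
        payload.update(overrides)
        return MonteCarloConfig(**payload)


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str
    out_dir: str = "outputs"
    allometry: AllometryConfig = AllometryConfig()
    monte_carlo: MonteCarloBlock = MonteCarloBlock()
    per_food_intake: bool = True  # Sum p/AE convention; False = mean-AE
    clamp_bii: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_and_validate(config_path: str | Path) -> tuple[RunConfig, WorldData]:
    """Parse the config, load the bundle, and fail with every problem listed."""
    path = Path(config_path)
    if not path.exists():
        raise ValidationError(f"config file {path} does not exist")
    cfg = RunConfig.from_yaml(path)
    base = path.parent / cfg.input_dir if not Path(cfg.input_dir).is_absolute() else Path(cfg.input_dir)
    world = io.read_world(base)
    return cfg, world
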