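"""Run configuration: YAML/JSON parsing with strict schema validation.

A configuration file has up to four sections::

    model:
      parameters: {vmax_acc: 1.5, ...}      # ModelParams overrides
      initial:    {holo-ACP: 100.0, ...}    # initial-state overrides (µM)
    protocol:
      fatty_acid: palmitate                 # or fed_species: C16:0-CoA
      clamp_value_uM: 30.0
      t_step_s: 8000.0
    solver:
      rtol: 1.0e-8
      atol: 1.0e-12
      t_max_s: 200000.0
      post_window_s: 3600.0
    seed: 0

Every section is optional; unknown keys anywhere are rejected.  The
resolved configuration (all defaults made explicit) can be serialised
back with :meth:`RunConfig.to_dict` and is logged by the CLI so a run is
exactly reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .engine import DEFAULT_CLAMP_UM, DEFAULT_T_STEP, FATTY_ACID_TO_COA
from .model import ModelParams, ModelSpec, StateVector, build_model

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameters: dict[str, Any] = Field(default_factory=dict)
    initial: dict[str, float] = Field(default_factory=dict)


class ProtocolSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fatty_acid: Optional[str] = None
    fed_species: Optional[str] = None
    clamp_value_uM: float = DEFAULT_CLAMP_UM
    t_step_s: float = DEFAULT_T_STEP

    @field_validator("fatty_acid")
    @classmethod
    def _known_fatty_acid(cls, v):
        if v is not None and v not in FATTY_ACID_TO_COA:
            raise ValueError(
                f"unknown fatty acid {v!r}; choose from "
                f"{sorted(FATTY_ACID_TO_COA)}")
        return v

    @field_validator("fed_species")
    @classmethod
    def _known_species(cls, v):
        if v is not None and v not in FATTY_ACID_TO_COA.values():
            raise ValueError(
                f"fed_species must be one of "
                f"{sorted(FATTY_ACID_TO_COA.values())}, got {v!r}")
        return v

    def resolved_species(self) -> str:
        if self.fed_species is not None:
            return self.fed_species
        if self.fatty_acid is not None:
            return FATTY_ACID_TO_COA[self.fatty_acid]
        raise ValueError("protocol needs either fatty_acid or fed_species")


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rtol: float = 1e-8
    atol: float = 1e-12
    t_max_s: float = 2e5
    post_window_s: float = 3600.0


class RunConfig(BaseModel):
    """Validated configuration for a simulation run."""

    model_config = ConfigDict(extra="forbid")

    model: ModelSection = Field(default_factory=ModelSection)
    protocol: Optional[ProtocolSection] = None
    solver: SolverSection = Field(default_factory=SolverSection)
    seed: int = 0

    def build_model(self) -> ModelSpec:
        return build_model(self.model.parameters or None)

    def initial_state(self, model: ModelSpec) -> StateVector:
        return model.initial_state(self.model.initial or None)

    def to_dict(self) -> dict:
        """Effective configuration with every default resolved, including
        the full model parameter set."""
        out = self.model_dump()
        params = ModelParams(**self.model.parameters) if self.model.parameters \
            else ModelParams()
        out["model"]["parameters"] = {
            k: getattr(params, k) for k in ModelParams.__dataclass_fields__
        }
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        config = RunConfig.model_validate(raw)
        # surface model-parameter errors (unknown names, bad values) early
        config.build_model()
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return config
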