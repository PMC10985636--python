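"""Run configuration: a single validated mapping covering every stage.

Every stochastic operation receives a seed derived deterministically from
the global seed and its operation path, so a run is reproducible from the
config file alone. Unknown keys are rejected (typo safety) and the global
seed is mandatory.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "validate_config", "derive_seed",
           "load_config"]


class ConfigError(ValueError):
    """Itemized, human-readable configuration errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in errors))


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    n_train: int = Field(60, ge=1)
    n_test: int = Field(80, ge=1)
    shape: tuple[int, int, int] = (1, 64, 64)
    cspca_prevalence: float = Field(0.5, ge=0.0, le=1.0)
    train_grade_probs: tuple[float, float, float, float] = \
        (0.55, 0.15, 0.15, 0.15)
    contrast_margin_sigmas: float = Field(3.0, gt=0)


class ModelSection(_Section):
    epochs: int = Field(20, ge=1)
    gland_epochs: int = Field(10, ge=1)
    batch_size: int = Field(8, ge=1)
    lr: float = Field(2e-3, gt=0)
    w_overlap: float = Field(1.0, ge=0)
    w_ce: float = Field(1.0, ge=0)
    width: int = Field(8, ge=2)
    folds: int = Field(5, ge=2)
    pos_weight: float = Field(10.0, ge=1)


class NoiseSection(_Section):
    epsilon: float = Field(0.02, gt=0)
    iters: int = Field(10, ge=1)
    step: float = Field(0.004, gt=0)
    lambda_style: float = Field(200.0, ge=0)
    lambda_content: float = Field(100.0, ge=0)
    lambda_adv: float = Field(1.0, ge=0)
    restrict_to_body: bool = True


class ScheduleSection(_Section):
    refresh_interval: int = Field(4, ge=1)
    mix_fraction: float = Field(0.5, ge=0.0, le=1.0)
    warmup: int = Field(4, ge=0)


class EvalSection(_Section):
    threshold: float = Field(0.45, gt=0, lt=1)
    min_overlap: float = Field(0.10, gt=0, le=1)
    min_size: int = Field(2, ge=1)
    bootstrap_b: int = Field(500, ge=100)


class RunConfig(_Section):
    seed: int
    verbosity: int = Field(1, ge=0, le=2)
    phantom: PhantomSection = PhantomSection()
    model: ModelSection = ModelSection()
    noise: NoiseSection = NoiseSection()
    schedule: ScheduleSection = ScheduleSection()
    evaluation: EvalSection = EvalSection()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"),
                              sort_keys=True)


def derive_seed(global_seed: int, op_path: str) -> int:
    """Deterministic per-operation seed below 2**31."""
    crc = zlib.crc32(op_path.encode())
    ss = np.random.SeedSequence([int(global_seed), crc])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _format_pydantic(e: ValidationError) -> list[str]:
    out = []
    for err in e.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def validate_config(path) -> RunConfig:
    """Load and validate a YAML config file; raise :class:`ConfigError`
    with one message per problem."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigError([f"YAML parse error: {e}"]) from e
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        raise ConfigError(_format_pydantic(e)) from e


def load_config(mapping: dict | None = None, **overrides) -> RunConfig:
    """Build a config from a mapping/kwargs (programmatic entry point)."""
    raw = dict(mapping or {})
    raw.update(overrides)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        raise ConfigError(_format_pydantic(e)) from e
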