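"""Scenario configuration: YAML/JSON files with strict key checking."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .engine import RandomInputs, TimeGrid
from .model import ParameterSet

__all__ = ["ScenarioConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Malformed scenario configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamConfig(_Strict):
    initial_challenge_stressor: float = 2.71
    expected_challenge_stress: float = 0.0
    initial_equilibrium_level: float = 0.0
    opponent_process_rate: float = 0.5
    importance_challenge_appraisal: float = 0.23
    importance_strain: float = 0.29
    base_importance_coping: float = 0.29
    base_importance_ocb: float = 0.2
    exchange_orientation: float = 0.51
    expected_satisfaction_init: float = 0.0
    new_task_workload: float = 0.0
    new_task_frequency: float = 0.0


class TimeConfig(_Strict):
    initial_time: float = 0.0
    final_time: float = 100.0
    dt: float = 1.0


class RandomConfig(_Strict):
    mode: Literal["stochastic", "mean"] = "stochastic"
    seed: int = 0


class ScenarioConfig(_Strict):
    """Resolved scenario: parameters, time grid, randomness, experiment."""

    params: ParamConfig = ParamConfig()
    time: TimeConfig = TimeConfig()
    random: RandomConfig = RandomConfig()
    experiment: str = "run"
    output_dir: str = "."

    def to_parameter_set(self) -> ParameterSet:
        return ParameterSet(**self.params.model_dump())

    def to_time_grid(self) -> TimeGrid:
        return TimeGrid(**self.time.model_dump())

    def to_random_inputs(self) -> RandomInputs:
        return RandomInputs(mode=self.random.mode, seed=self.random.seed)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML or JSON scenario file, filling defaults.

    An empty file yields the baseline scenario. Unknown keys and type
    mismatches raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ScenarioConfig(**raw)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}"
            for e in err.errors()
        )
        raise ConfigError(f"{path}: {details}") from err
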