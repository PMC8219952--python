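"""Run configuration: every numeric parameter of the pipeline in one place.

Defaults reproduce the evaluation conditions used throughout the package:
CAPRI quality cut-points, benchmark difficulty cut-points, FCC clustering
parameters and the scenario/selection cutoffs.  A YAML file can override
any subset; unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .clustering import ClusterParams
from .metrics import CapriThresholds, DifficultyThresholds, ScenarioSpec


@dataclass
class RunConfig:
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    capri: CapriThresholds = field(default_factory=CapriThresholds)
    difficulty: DifficultyThresholds = field(default_factory=DifficultyThresholds)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    min_identity: float = 0.9
    seed: int = 0
    max_translation: float = 20.0
    verbosity: str = "INFO"

    def __post_init__(self):
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_translation <= 0:
            raise ValueError("max_translation must be positive")


_SECTIONS = {
    "scenario": ScenarioSpec,
    "capri": CapriThresholds,
    "difficulty": DifficultyThresholds,
    "cluster": ClusterParams,
}


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {cls.__name__}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, then overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key/value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    kwargs = {}
    top_level = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_level
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
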