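"""Run configuration: YAML schema, validation, and echoing for provenance."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .listeners import ConfigError, GeneratingParams
from .staircase import StaircaseConfig

_PARAM_FIELDS = {f.name for f in dataclasses.fields(GeneratingParams)}
_STAIRCASE_FIELDS = {f.name for f in dataclasses.fields(StaircaseConfig)}


@dataclass
class RunConfig:
    """Everything needed to regenerate a run.

    ``params`` and ``staircase`` hold field-level overrides of the
    generating model and the adaptive-procedure defaults; unknown keys are
    rejected anywhere in the schema.
    """

    seed: int = 0
    n_listeners: int = 14
    mode: str = "threshold_level"
    demographics: str = "parametric"
    scoring: str = "keyword"
    replicates: int = 200
    out_dir: str = "results/run"
    exhaust_pool: bool = False
    include_training: bool = False
    candidates: list = field(default_factory=lambda: ["age", "duration_deafness"])
    params: dict = field(default_factory=dict)
    staircase: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("trial_level", "threshold_level"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.demographics not in ("fixture", "parametric"):
            raise ConfigError(f"unknown demographics source {self.demographics!r}")
        if self.scoring not in ("keyword", "sentence"):
            raise ConfigError(f"unknown scoring {self.scoring!r}")
        bad = set(self.params) - _PARAM_FIELDS
        if bad:
            raise ConfigError(f"unknown generating-parameter keys: {sorted(bad)}")
        bad = set(self.staircase) - _STAIRCASE_FIELDS
        if bad:
            raise ConfigError(f"unknown staircase keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def generating_params(self) -> GeneratingParams:
        p = dict(self.params)
        if "learning_curve" in p:
            p["learning_curve"] = tuple(p["learning_curve"])
        return GeneratingParams(**p)

    def staircase_config(self) -> StaircaseConfig:
        return StaircaseConfig(**self.staircase)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
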