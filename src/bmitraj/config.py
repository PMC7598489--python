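"""Pipeline configuration: defaults, YAML loading, unknown-key rejection."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .synth import ConfigError, SimConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """End-to-end run configuration.  Every field has a default.

    Either ``simulate`` is set (the run starts by generating a cohort) or
    ``subjects_path``/``exams_path`` point at existing CSVs.
    """

    seed: int = 0
    out_dir: str = "out"
    simulate: SimConfig | None = None
    subjects_path: str | None = None
    exams_path: str | None = None
    qc_strict: bool = True
    tie_rule: str = "earliest"
    rwg_threshold: float = 5.1
    bmi_reference_path: str | None = None  # external percentile thresholds
    outcome: str = "ar_before_57"
    min_curve_n: int = 100

    def __post_init__(self) -> None:
        if self.tie_rule not in ("earliest", "latest"):
            raise ConfigError(f"tie_rule must be earliest|latest, got {self.tie_rule!r}")
        if self.outcome != "ar_before_57":
            raise ConfigError(f"unknown outcome {self.outcome!r}")

    def validate_inputs(self) -> None:
        if self.simulate is None:
            if not (self.subjects_path and self.exams_path):
                raise ConfigError("need either a simulate block or input paths")
            for p in (self.subjects_path, self.exams_path):
                if not Path(p).exists():
                    raise ConfigError(f"input file not found: {p}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        sim = kwargs.get("simulate")
        if sim is not None and not isinstance(sim, SimConfig):
            if not isinstance(sim, Mapping):
                raise ConfigError("simulate block must be a mapping")
            kwargs["simulate"] = SimConfig.from_mapping(sim)
        return cls(**kwargs)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_mapping(data)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"]["exam_ages"] = list(self.simulate.exam_ages)
            d["simulate"]["exposures"] = dict(self.simulate.exposures)
        return d
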