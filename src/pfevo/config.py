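"""Structured run configuration (YAML) for the command-line pipeline."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fitness import FitnessParams, ExpressionModes
from .simulator import SimConfig
from .switching import SwitchingParams
from .synthetic import SynthConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**section)


@dataclass
class RunConfig:
    """Top-level configuration shared by all pipeline commands."""

    seed: int = 0
    outdir: str = "pfevo_out"
    conditions: tuple = ("D0Z0", "DiZ0", "D2Z0", "D0Z2", "DiZ2", "D2Z2")
    log_level: str = "INFO"
    fitness: FitnessParams = field(default_factory=FitnessParams)
    switching: SwitchingParams = field(default_factory=SwitchingParams)
    modes: ExpressionModes = field(default_factory=ExpressionModes)
    sim: SimConfig = field(default_factory=SimConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        sections = {
            "fitness": FitnessParams, "switching": SwitchingParams,
            "modes": ExpressionModes, "sim": SimConfig, "synth": SynthConfig,
        }
        kwargs = {}
        for name, sub_cls in sections.items():
            if name in raw:
                section = raw.pop(name)
                if isinstance(section, dict):
                    kwargs[name] = _build(sub_cls, section, name)
                else:
                    kwargs[name] = section
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw, **kwargs)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
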