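"""Run configuration: nested, strictly validated, YAML round-trippable.

A :class:`RunConfig` mirrors every stage's parameter dataclass. Unknown keys
anywhere in the file are rejected before any computation, and
``to_dict``/``from_dict`` round-trip losslessly. A single master seed
deterministically derives the per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .dynamics import ContractionSchedule, LangevinParams, RemodelRule, BondPotential
from .elastostatics import ElasticParams
from .geometry import PatternSpec
from .netgen import ClusterSpec, NetworkSpec
from .synthmicro import RenderSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "stage_seeds"]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "pattern": PatternSpec,
    "network": NetworkSpec,
    "cluster": ClusterSpec,
    "potential": BondPotential,
    "schedule": ContractionSchedule,
    "remodel": RemodelRule,
    "langevin": LangevinParams,
    "elastic": ElasticParams,
    "render": RenderSpec,
}


@dataclass(frozen=True)
class RunConfig:
    pattern: PatternSpec
    network: NetworkSpec = NetworkSpec()
    cluster: ClusterSpec = ClusterSpec()
    potential: BondPotential = BondPotential()
    schedule: ContractionSchedule = ContractionSchedule()
    remodel: RemodelRule = RemodelRule()
    langevin: LangevinParams = LangevinParams()
    elastic: ElasticParams = ElasticParams()
    render: RenderSpec = RenderSpec()
    seed: int = 0

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        d["seed"] = self.seed
        # tuples are not YAML-stable; normalize to lists
        if d["render"]["shape"] is not None:
            d["render"]["shape"] = list(d["render"]["shape"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(data) - set(_SECTIONS) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "pattern" not in data:
            raise ConfigError("config must contain a 'pattern' section")
        kwargs: dict[str, Any] = {}
        for name, klass in _SECTIONS.items():
            if name not in data:
                continue
            section = data[name]
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - valid
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            section = dict(section)
            if name == "render" and isinstance(section.get("shape"), list):
                section["shape"] = tuple(section["shape"])
            try:
                kwargs[name] = klass(**section)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid section {name!r}: {exc}") from exc
        if "seed" in data:
            if not isinstance(data["seed"], int):
                raise ConfigError("seed must be an integer")
            kwargs["seed"] = data["seed"]
        return cls(**kwargs)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from one master seed."""
    names = ("network", "pattern", "langevin", "render")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def apply_overrides(data: dict, overrides: list[str]) -> dict:
    """Apply dotted ``section.key=value`` overrides to a config mapping."""
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        dotted, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        keys = dotted.split(".")
        node = data
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot descend into {dotted!r}")
        node[keys[-1]] = value
    return data
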