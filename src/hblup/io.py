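"""Run-configuration loading and tabular output helpers."""

from __future__ import annotations

import dataclasses
import json

import yaml

from .simulate import SimulationConfig


def load_config(path) -> SimulationConfig:
    """Read a YAML run configuration into a :class:`SimulationConfig`.

    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key in ("programs", "races"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(cfg: SimulationConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    data["programs"] = list(data["programs"])
    data["races"] = list(data["races"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
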