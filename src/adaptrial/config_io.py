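"""YAML config parsing and result serialisation for the CLI."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .designs import TrialDesign, FixedDesign, ScenarioConfig

__all__ = [
    "load_design_config",
    "load_scenario_config",
    "dump_design_config",
    "dump_scenario_config",
]

_DESIGN_FIELDS = {f.name for f in dataclasses.fields(TrialDesign)}
_FIXED_FIELDS = {f.name for f in dataclasses.fields(FixedDesign)} | {"method"}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def _load_mapping(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of configuration keys")
    return data


def _check_keys(data: dict, allowed: set, required: set, path):
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    missing = required - set(data)
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")


def load_design_config(path) -> TrialDesign | FixedDesign:
    """Load a design config.  ``method: fixed`` yields the benchmark
    :class:`FixedDesign`; anything else a validated
    :class:`TrialDesign` (method-specific threshold presence is
    enforced by the dataclass)."""
    data = _load_mapping(path)
    if data.get("method") == "fixed":
        _check_keys(data, _FIXED_FIELDS, set(), path)
        data = {k: v for k, v in data.items() if k != "method"}
        return FixedDesign(**data)
    _check_keys(data, _DESIGN_FIELDS,
                {"method", "k_F", "k_S", "d_L", "d_U"}, path)
    return TrialDesign(**data)


def load_scenario_config(path) -> ScenarioConfig:
    data = _load_mapping(path)
    _check_keys(data, _SCENARIO_FIELDS, {"median_C", "median_E"}, path)
    return ScenarioConfig(**data)


def dump_design_config(design: TrialDesign | FixedDesign, path):
    data = {k: v for k, v in dataclasses.asdict(design).items()
            if v is not None}
    if isinstance(design, FixedDesign):
        data["method"] = "fixed"
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def dump_scenario_config(scenario: ScenarioConfig, path):
    data = {k: v for k, v in dataclasses.asdict(scenario).items()
            if v is not None}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
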