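"""Run configuration: YAML parsing and validation.

A config file mirrors :class:`~partmig.params.SimParams` and
:class:`~partmig.scenarios.Scenario`; every omitted parameter falls back to
its standard value. Example::

    params:
      K: 100
      s_m: 0.5
    scenario: compl-full-survup        # catalog name, or a mapping
    n_generations: 1000
    base_seed: 1
    output_dir: out
    record_every: 1
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .params import SimParams
from .scenarios import Scenario, scenario_by_name


class ConfigError(ValueError):
    """Raised for unknown keys, out-of-range values, or invalid scenarios."""


_TOP_KEYS = {
    "params",
    "scenario",
    "n_generations",
    "base_seed",
    "output_dir",
    "record_every",
    "write_per_x",
}


@dataclass
class RunConfig:
    params: SimParams
    scenario: Scenario
    n_generations: int = 1000
    base_seed: int = 1
    output_dir: str = "partmig_out"
    record_every: int = 1
    write_per_x: bool = True

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        if self.scenario.change != "none" and (
            self.scenario.change_generation > self.n_generations
        ):
            raise ConfigError(
                "change_generation exceeds n_generations for scenario "
                f"{self.scenario.name!r}"
            )


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")


def _build_params(block: dict) -> SimParams:
    _check_keys(block, {f.name for f in dataclasses.fields(SimParams)}, "params")
    try:
        return SimParams(**block)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid params: {exc}") from exc


def _build_scenario(block, defaults: dict) -> Scenario:
    if isinstance(block, str):
        try:
            return scenario_by_name(block, **defaults)
        except KeyError as exc:
            raise ConfigError(str(exc)) from exc
    if not isinstance(block, dict):
        raise ConfigError("scenario must be a catalog name or a mapping")
    _check_keys(block, {f.name for f in dataclasses.fields(Scenario)}, "scenario")
    merged = {**defaults, **block}
    if "name" not in merged:
        merged["name"] = "custom"
    try:
        return Scenario(**merged)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid scenario: {exc}") from exc


def config_from_mapping(doc: dict | None) -> RunConfig:
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "config")
    params = _build_params(doc.get("params") or {})
    scenario = _build_scenario(
        doc.get("scenario", {"name": "compl-full", "init_region": "complete",
                             "init_diversity": "maximum", "change": "none",
                             "change_generation": 0}),
        defaults={},
    )
    return RunConfig(
        params=params,
        scenario=scenario,
        n_generations=int(doc.get("n_generations", 1000)),
        base_seed=int(doc.get("base_seed", 1)),
        output_dir=str(doc.get("output_dir", "partmig_out")),
        record_every=int(doc.get("record_every", 1)),
        write_per_x=bool(doc.get("write_per_x", True)),
    )


def parse_config(path) -> RunConfig:
    """Parse and fully validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_mapping(doc)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML (inverse of :func:`parse_config`)."""
    doc = {
        "params": cfg.params.to_dict(),
        "scenario": dataclasses.asdict(cfg.scenario),
        "n_generations": cfg.n_generations,
        "base_seed": cfg.base_seed,
        "output_dir": cfg.output_dir,
        "record_every": cfg.record_every,
        "write_per_x": cfg.write_per_x,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
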