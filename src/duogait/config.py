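"""Run configuration: schema-validated YAML/dict handling.

A :class:`RunConfig` gathers the simulation spec, detector thresholds
and ML settings behind a single seed.  Mappings are validated
recursively against the dataclass field names — unknown keys are
rejected before any stage runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .classify import MLConfig
from .imu import BoutConfig, PeakDetectionParams
from .insole import ForceThresholds, PreprocessConfig
from .simulate import (ImpairmentEffect, ImuRenderParams, InsoleRenderParams,
                       NoiseSpec, SimulationSpec)


class ConfigError(ValueError):
    pass


def _build(cls, mapping, path="config"):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if mapping is None:
        return cls()
    if is_dataclass(mapping):
        return mapping
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(mapping) - set(known)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}; "
                          f"allowed: {sorted(known)}")
    kwargs = {}
    for key, value in mapping.items():
        ftype = known[key].type
        target = _NESTED.get((cls, key))
        if target is not None:
            kwargs[key] = _build(target, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v
                                for v in value)
        else:
            kwargs[key] = value
        del ftype
    return cls(**kwargs)


_NESTED = {
    (SimulationSpec, "impairment"): ImpairmentEffect,
    (SimulationSpec, "noise"): NoiseSpec,
    (SimulationSpec, "insole"): InsoleRenderParams,
    (SimulationSpec, "imu"): ImuRenderParams,
}


@dataclass
class RunConfig:
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    thresholds: ForceThresholds = field(default_factory=ForceThresholds)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    peaks: PeakDetectionParams = field(default_factory=PeakDetectionParams)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    seed: int = 0
    printed_formula: bool = False
    make_plots: bool = False
    verbosity: int = 1

    def validate(self) -> None:
        self.simulation.validate()
        self.thresholds.validate()
        self.peaks.validate()

    def with_seed(self, seed: int | None) -> "RunConfig":
        """Propagate an overriding seed to every stage."""
        if seed is None:
            return self
        return dataclasses.replace(
            self, seed=seed,
            simulation=dataclasses.replace(self.simulation, seed=seed),
            ml=dataclasses.replace(self.ml, seed=seed))

    def provenance(self) -> dict:
        """Full parameter record for the run report (no timestamps)."""
        return {"seed": self.seed,
                "printed_formula": self.printed_formula,
                "simulation": dataclasses.asdict(self.simulation),
                "thresholds": dataclasses.asdict(self.thresholds),
                "preprocess": dataclasses.asdict(self.preprocess),
                "peaks": dataclasses.asdict(self.peaks),
                "bouts": dataclasses.asdict(self.bouts),
                "ml": dataclasses.asdict(self.ml)}


_SECTIONS = {
    "simulation": SimulationSpec,
    "thresholds": ForceThresholds,
    "preprocess": PreprocessConfig,
    "peaks": PeakDetectionParams,
    "bouts": BoutConfig,
    "ml": MLConfig,
}


def config_from_mapping(mapping: dict | None) -> RunConfig:
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(mapping) - set(_SECTIONS) - {"seed", "printed_formula",
                                               "make_plots", "verbosity"}
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build(cls, mapping.get(name), f"config.{name}")
    for scalar in ("seed", "printed_formula", "make_plots", "verbosity"):
        if scalar in mapping:
            kwargs[scalar] = mapping[scalar]
    cfg = RunConfig(**kwargs)
    cfg = cfg.with_seed(cfg.seed)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    return config_from_mapping(mapping)
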