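"""Declarative analysis configuration (YAML) with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["AnalysisConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


# Allowed keys per block; None means a scalar leaf, a dict means nesting.
_SCHEMA: dict[str, Any] = {
    "seed": None,
    "paths": {"roi_table": None, "timeseries": None, "counts": None, "output_dir": None},
    "constants": {
        "n15_natural_fraction": None,
        "c13_natural_fraction": None,
        "cn_ratio": None,
        "allometry_a": None,
        "allometry_b": None,
        "alpha": None,
        "poisson_threshold": None,
        "dilution_correction": None,
    },
    "modes": {"growth_model": None, "labeling_source": None, "quota_mode": None},
    "incubation": {"t_days": None},
    "populations": "list",
    "thermo": {
        "temperature_k": None,
        "ph": None,
        "concentrations": "map",
        "reactions": "list",
    },
}

_POPULATION_KEYS = {"taxon", "shape", "length_um", "width_um", "substrate", "reaction"}
_REACTION_KEYS = {"name", "taxon", "delta_g_kj_mol", "stoichiometry", "formation_energies"}


@dataclass
class AnalysisConfig:
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    constants: dict[str, float] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)
    incubation: dict[str, float] = field(default_factory=dict)
    populations: list[dict] = field(default_factory=list)
    thermo: dict[str, Any] = field(default_factory=dict)

    def constant(self, name: str, default: float) -> float:
        value = float(self.constants.get(name, default))
        if value <= 0:
            raise ConfigError(f"constant {name!r} must be positive, got {value}")
        return value

    def mode(self, name: str, default: str) -> str:
        return str(self.modes.get(name, default))


def _check_keys(data: Mapping, schema: Mapping, context: str) -> None:
    for key, value in data.items():
        if key not in schema:
            raise ConfigError(f"unknown key {context}{key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{context}{key} must be a mapping")
            _check_keys(value, sub, f"{context}{key}.")


def _check_item_keys(items: list, allowed: set[str], context: str) -> None:
    for i, item in enumerate(items or []):
        if not isinstance(item, Mapping):
            raise ConfigError(f"{context}[{i}] must be a mapping")
        unknown = set(item) - allowed
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}[{i}]")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _SCHEMA, "")
    _check_item_keys(raw.get("populations", []), _POPULATION_KEYS, "populations")
    thermo = raw.get("thermo", {}) or {}
    _check_item_keys(thermo.get("reactions", []), _REACTION_KEYS, "thermo.reactions")
    return AnalysisConfig(
        seed=int(raw.get("seed", 0)),
        paths=dict(raw.get("paths", {}) or {}),
        constants=dict(raw.get("constants", {}) or {}),
        modes=dict(raw.get("modes", {}) or {}),
        incubation=dict(raw.get("incubation", {}) or {}),
        populations=list(raw.get("populations", []) or []),
        thermo=dict(thermo),
    )
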