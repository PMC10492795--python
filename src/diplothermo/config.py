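"""Run configuration: YAML schema, validation and defaults.

An empty config file is valid and resolves to the default regime: Model 2,
dG_folding_wt = -2, dG_binding_wt = -5 kcal/mol, ligand:protein ratio 1,
the default ddG grid and linear linking.  Unknown keys are rejected with
their field path so typos fail loudly before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .flow import GateSpec
from .grids import BINDING, GridSpec
from .linking import LinkingSpec
from .metrics import BETWEEN, WITHIN
from .thermo import EnergyParams, SystemConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "config_to_dict"]

_VALID_COMBINATIONS = (WITHIN, BETWEEN, "compound_het")


class ConfigError(ValueError):
    """A configuration value or key failed validation."""


@dataclass(frozen=True)
class RunConfig:
    model: int = 2
    energy: EnergyParams = field(default_factory=EnergyParams)
    system: SystemConfig = field(default_factory=SystemConfig)
    grid: GridSpec = field(default_factory=GridSpec.ddg)
    linking: LinkingSpec = field(default_factory=LinkingSpec)
    combinations: tuple[str, ...] = (WITHIN, BETWEEN)
    gate: GateSpec = field(default_factory=GateSpec)
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in (1, 2):
            raise ConfigError(f"model: must be 1 or 2, got {self.model}")
        bad = [c for c in self.combinations if c not in _VALID_COMBINATIONS]
        if bad:
            raise ConfigError(
                f"combinations: unknown kinds {bad}; valid: {list(_VALID_COMBINATIONS)}"
            )
        if self.model == 1 and self.grid.mutation_type == BINDING:
            raise ConfigError(
                "grid.mutation_type: binding mutations are undefined in Model 1"
            )
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed: must be an integer, got {self.seed!r}")


_SECTIONS = {
    "energy": EnergyParams,
    "system": SystemConfig,
    "grid": GridSpec,
    "linking": LinkingSpec,
    "gate": GateSpec,
}


def _build_section(name: str, cls, data: Any):
    if not isinstance(data, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"{name}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file, resolving all defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    allowed_top = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(allowed_top)}"
        )
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(key, _SECTIONS[key], value)
        elif key == "combinations":
            if not isinstance(value, (list, tuple)):
                raise ConfigError("combinations: expected a list")
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(cfg: RunConfig) -> dict:
    """Flatten a RunConfig to plain JSON-serializable types (for manifests)."""
    out: dict[str, Any] = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if f.name in _SECTIONS:
            out[f.name] = {sf.name: getattr(v, sf.name) for sf in fields(v)}
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out
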