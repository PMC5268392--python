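"""Simulation and experiment configuration.

Configuration files are flat key–value YAML documents.  A file containing
``replicates`` or ``conditions`` is parsed as an :class:`ExperimentConfig`,
otherwise as a :class:`SimulationConfig`.  Unknown keys are rejected so that
typos never silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "Condition",
    "ExperimentConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for missing, unknown or out-of-range configuration values."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a single simulation run.

    Parameters
    ----------
    world_size
        Side length L of the square periodic world (length units).
    n_agents
        Number of agents; constant over a run (no birth or death).
    n_rounds
        Number of rounds to simulate.
    memory_length
        Maximum number of past encounters remembered per pair of agents
        (the individual-recognition window M, 0–30 in the original study).
    memory_modifier
        Probability-weight increment m per remembered interaction of a
        type, in [0, 0.5] (0.5% to 50% per interaction).
    interaction_radius
        Distance within which two agents can interact (length units).
    step_length
        Distance moved per round (length units).
    ir_enabled
        Whether agents record encounters at all.  ``False`` is behaviorally
        identical to ``memory_length=0``.
    seed
        RNG seed; a run is a deterministic function of (config, seed).
    snapshot_interval
        Rounds between recorded position snapshots (round 0 always kept).
    """

    world_size: float
    n_agents: int
    n_rounds: int
    memory_length: int = 20
    memory_modifier: float = 0.05
    interaction_radius: float = 1.0
    step_length: float = 1.0
    ir_enabled: bool = True
    seed: int = 0
    snapshot_interval: int = 1

    def __post_init__(self) -> None:
        if self.world_size <= 0:
            raise ConfigError(f"world_size must be > 0, got {self.world_size}")
        if self.n_agents < 0:
            raise ConfigError(f"n_agents must be >= 0, got {self.n_agents}")
        if self.n_rounds < 0:
            raise ConfigError(f"n_rounds must be >= 0, got {self.n_rounds}")
        if self.memory_length < 0 or int(self.memory_length) != self.memory_length:
            raise ConfigError(
                f"memory_length must be a non-negative integer, got {self.memory_length}"
            )
        if not 0.0 <= self.memory_modifier <= 0.5:
            raise ConfigError(
                f"memory_modifier must be in [0, 0.5], got {self.memory_modifier}"
            )
        if self.interaction_radius <= 0:
            raise ConfigError(
                f"interaction_radius must be > 0, got {self.interaction_radius}"
            )
        if self.interaction_radius >= self.world_size / 2:
            raise ConfigError(
                "interaction_radius must be < world_size/2 "
                f"(got {self.interaction_radius} with world_size {self.world_size})"
            )
        if self.step_length < 0:
            raise ConfigError(f"step_length must be >= 0, got {self.step_length}")
        if self.snapshot_interval < 1:
            raise ConfigError(
                f"snapshot_interval must be >= 1, got {self.snapshot_interval}"
            )
        if not 0 <= int(self.seed) < 2**32:
            raise ConfigError(f"seed must be in [0, 2**32), got {self.seed}")

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        return cls(**_checked_kwargs(cls, data))


@dataclass(frozen=True)
class Condition:
    """One experimental condition: an (ir_enabled, M, m) triple."""

    ir_enabled: bool
    memory_length: int
    memory_modifier: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            lab = (
                f"IR(M={self.memory_length},m={self.memory_modifier:g})"
                if self.ir_enabled
                else "no-IR"
            )
            object.__setattr__(self, "label", lab)

    def apply(self, base: SimulationConfig) -> SimulationConfig:
        return base.replace(
            ir_enabled=self.ir_enabled,
            memory_length=self.memory_length,
            memory_modifier=self.memory_modifier,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ExperimentConfig:
    """A replicated IR vs no-IR experiment over a grid of conditions.

    Replicate seeds are derived deterministically from ``master_seed``
    (see :func:`socsim.experiment.replicate_seed`).
    """

    base: SimulationConfig
    conditions: tuple[Condition, ...]
    replicates: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if len(self.conditions) == 0:
            raise ConfigError("condition grid must be nonempty")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def to_dict(self) -> dict[str, Any]:
        d = self.base.to_dict()
        d.pop("ir_enabled")
        d.pop("memory_length")
        d.pop("memory_modifier")
        d.pop("seed")
        d["replicates"] = self.replicates
        d["master_seed"] = self.master_seed
        d["conditions"] = [c.to_dict() for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ExperimentConfig":
        data = dict(data)
        replicates = data.pop("replicates", 10)
        master_seed = data.pop("master_seed", 0)
        raw_conditions = data.pop("conditions", None)
        if raw_conditions is None:
            # default contrast: IR on vs off at the base memory parameters
            mem = data.get("memory_length", 20)
            mod = data.get("memory_modifier", 0.05)
            conditions = (
                Condition(False, 0, 0.0),
                Condition(True, mem, mod),
            )
        else:
            conditions = tuple(
                Condition(**_checked_kwargs(Condition, c)) for c in raw_conditions
            )
        base = SimulationConfig.from_dict(data)
        return cls(
            base=base,
            conditions=conditions,
            replicates=replicates,
            master_seed=master_seed,
        )


def _checked_kwargs(cls: type, data: Mapping[str, Any]) -> dict[str, Any]:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; valid keys: {sorted(names)}"
        )
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING  # type: ignore[misc]
    }
    missing = required - set(data)
    if missing:
        raise ConfigError(f"missing required {cls.__name__} keys: {sorted(missing)}")
    return dict(data)


def load_config(path: str | Path) -> SimulationConfig | ExperimentConfig:
    """Load a simulation or experiment configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a flat key-value document")
    if "replicates" in data or "conditions" in data or "master_seed" in data:
        return ExperimentConfig.from_dict(data)
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig | ExperimentConfig, path: str | Path) -> None:
    """Write a fully resolved configuration back to YAML (round-trips)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
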