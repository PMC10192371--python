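"""Run configuration: parameter schema, validation and flat-YAML round-tripping.

A run is described by three pieces:

* :class:`SimulationParams` -- global constants (grid size, metabolic rates,
  energy threshold, portion size, seed, ...).
* :class:`FoodSchedule` -- the food-regeneration regime, either a constant
  per-cell regeneration probability ``p_g`` or alternating abundance/famine
  periods drawn from normal distributions.
* a population spec -- a list of :class:`PopulationGroup` entries, each one a
  block of identical agents (count, accumulation level, foraging strategy,
  decision heuristic).

Config files are flat ``key: value`` YAML documents; the only nested structure
is the ``population`` list.  An explicit ``seed`` is mandatory so that every
run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "STRATEGIES",
    "HEURISTICS",
    "ConfigError",
    "ValidationError",
    "SimulationParams",
    "FoodSchedule",
    "PopulationGroup",
    "RunConfig",
    "load_config",
    "save_config",
]

#: Foraging strategies: Static, Random Foraging, Directed Foraging, Feedback Foraging.
STRATEGIES = ("S", "RF", "DF", "FF")

#: Decision heuristics applied to the energy accumulation level.
HEURISTICS = ("repetition", "imitation", "inquiring")


class ConfigError(ValueError):
    """A config file is missing a required key or cannot be parsed."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass(frozen=True)
class SimulationParams:
    """Global simulation constants.

    Defaults are the baseline values used throughout the experiments
    (``E_s`` defaults to 2.0, the constant-environment setting; the seasonal
    experiments raise it to 3.0).
    """

    seed: int
    grid_side: int = 41
    E_T: float = 20.0          #: energy threshold between metabolic/movement regimes
    M_b: float = 0.05          #: base metabolic rate (per-step fraction)
    C_p: float = 0.01          #: energy cost of one act of perception
    C_m: float = 0.02          #: per-move fraction of body energy
    E_s: float = 2.0           #: energy per food portion ("portion size")
    initial_energy: float = 2.0
    n_steps: int | None = None  #: None => derive from the seasonal schedule
    replicate_count: int = 30

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        if self.grid_side < 3:
            raise ValidationError("grid_side must be >= 3 (torus needs 8 distinct neighbors)")
        if not 0.0 < self.M_b < 1.0:
            raise ValidationError("M_b must satisfy 0 < M_b < 1")
        if self.C_p < 0.0:
            raise ValidationError("C_p must be >= 0")
        if not 0.0 <= self.C_m < 1.0:
            raise ValidationError("C_m must satisfy 0 <= C_m < 1")
        if self.E_s <= 0.0:
            raise ValidationError("E_s must be > 0")
        if self.E_T <= 0.0:
            raise ValidationError("E_T must be > 0")
        if not self.E_s < self.E_T:
            raise ValidationError(
                "E_s must be < E_T (the uninhibited-movement band [E_s, E_T] must be non-empty)"
            )
        if self.initial_energy <= 0.0:
            raise ValidationError("initial_energy must be > 0")
        if self.n_steps is not None and self.n_steps < 0:
            raise ValidationError("n_steps must be >= 0")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")


@dataclass(frozen=True)
class FoodSchedule:
    """Food-regeneration regime.

    ``constant`` mode regenerates each empty cell with probability ``p_g``
    every step.  ``seasonal`` mode alternates abundance (p_g = 1) and famine
    (p_g = 0) periods, starting with abundance; period lengths are drawn from
    N(t_ab, std) and N(t_fam, std), rounded to the nearest integer and clipped
    below at 1.
    """

    mode: str = "constant"
    p_g: float | None = None
    t_ab: float = 60.0
    t_fam: float = 40.0
    std: float = 0.0
    n_cycles: int = 10

    def validate(self) -> None:
        if self.mode not in ("constant", "seasonal"):
            raise ValidationError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "constant":
            if self.p_g is None:
                raise ValidationError("constant schedule requires p_g")
            if not 0.0 <= self.p_g <= 1.0:
                raise ValidationError("p_g must lie in [0, 1]")
        else:
            if self.t_ab < 1 or self.t_fam < 1:
                raise ValidationError("t_ab and t_fam must be >= 1")
            if self.std < 0:
                raise ValidationError("std must be >= 0")
            if self.n_cycles < 1:
                raise ValidationError("n_cycles must be >= 1")


@dataclass(frozen=True)
class PopulationGroup:
    """A block of identical agents in the initial population."""

    count: int
    level: float
    strategy: str = "S"
    heuristic: str = "repetition"

    def validate(self, initial_energy: float) -> None:
        if self.count < 0:
            raise ValidationError("group count must be >= 0")
        if self.level <= 0:
            raise ValidationError("accumulation level must be > 0")
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.heuristic not in HEURISTICS:
            raise ValidationError(f"unknown heuristic {self.heuristic!r}")
        if self.count > 0 and initial_energy > self.level:
            raise ValidationError(
                "initial_energy exceeds the accumulation level of a group "
                "(energy must never exceed the storage ceiling)"
            )


@dataclass
class RunConfig:
    """A fully validated run description."""

    params: SimulationParams
    schedule: FoodSchedule
    population: list[PopulationGroup] = field(default_factory=list)

    def validate(self) -> None:
        self.params.validate()
        self.schedule.validate()
        if self.schedule.mode == "constant" and self.params.n_steps is None:
            raise ValidationError("constant-p_g runs require an explicit n_steps")
        for g in self.population:
            g.validate(self.params.initial_energy)
        if sum(g.count for g in self.population) <= 0:
            raise ValidationError("total initial population must be > 0")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = asdict(self.params)
        sched = asdict(self.schedule)
        if sched["mode"] == "seasonal":
            sched.pop("p_g")
        else:
            for k in ("t_ab", "t_fam", "std", "n_cycles"):
                sched.pop(k)
        d.update(sched)
        d["population"] = [asdict(g) for g in self.population]
        return d


_PARAM_KEYS = {
    "seed", "grid_side", "E_T", "M_b", "C_p", "C_m", "E_s",
    "initial_energy", "n_steps", "replicate_count",
}
_SCHED_KEYS = {"mode", "p_g", "t_ab", "t_fam", "std", "n_cycles"}


def _build(doc: dict[str, Any]) -> RunConfig:
    unknown = set(doc) - _PARAM_KEYS - _SCHED_KEYS - {"population"}
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "seed" not in doc:
        raise ConfigError("missing required key: seed (explicit seeds are mandatory)")
    if "population" not in doc or not doc["population"]:
        raise ConfigError("missing required key: population")

    try:
        params = SimulationParams(**{k: doc[k] for k in _PARAM_KEYS if k in doc})
        schedule = FoodSchedule(**{k: doc[k] for k in _SCHED_KEYS if k in doc})
        groups = [PopulationGroup(**g) for g in doc["population"]]
    except TypeError as exc:  # e.g. bad key inside a population entry
        raise ConfigError(str(exc)) from exc

    cfg = RunConfig(params=params, schedule=schedule, population=groups)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat-YAML run configuration.

    Raises :class:`ConfigError` for missing/unknown keys and
    :class:`ValidationError` for invariant violations.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} does not contain a key-value mapping")
    return _build(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a validated config back to flat YAML (round-trip safe)."""
    cfg.validate()
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
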