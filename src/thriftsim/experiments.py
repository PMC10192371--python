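"""Experiment presets and ensemble runners.

Three canonical experiments are packaged:

* **exp1** -- constant environments.  Pairs of accumulation levels (5 vs one
  of 6, 15, 55, 105; 840 agents each) compete for 500 steps under a fixed
  regeneration probability ``p_g``, swept over 0.1..1.0 (step 0.1) and
  0.01..0.15 (step 0.01), for each foraging strategy, with the repetition
  heuristic and E_s = 2.  The summary quantity is the survivor difference
  (higher level minus level 5) at the final step.

* **exp2** -- feast-famine environments.  Levels 55 and 105 (840 agents each)
  under E_s = 3 and a 10-cycle schedule of 60 abundance + 40 famine steps
  (period lengths N(60, STD) / N(40, STD), STD in {0, 1, 5}), 1000 steps,
  swept over strategies and decision heuristics.

* **exp3** -- as exp2 (FF strategy, STD = 0) with initial populations 1680,
  1260, 840 and 420 split equally between the two levels.

Each configuration is run as an ensemble of seeded replicates (30 by
default); replicate ``r`` uses ``master_seed + r`` and distinct
configurations within a sweep use ``master_seed + 100000 * config_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import HEURISTICS, STRATEGIES, FoodSchedule, PopulationGroup, RunConfig, SimulationParams
from .engine import run_simulation

__all__ = [
    "ExperimentPreset",
    "EXP1",
    "EXP2",
    "EXP3",
    "Ensemble",
    "exp1_config",
    "exp2_config",
    "exp3_config",
    "run_ensemble",
    "run_exp1",
    "run_exp2",
    "run_exp3",
]

#: p_g grid of experiment 1: 0.1..1.0 in steps of 0.1 plus 0.01..0.15 in steps of 0.01.
EXP1_PG_GRID = tuple(
    sorted({round(0.01 * k, 2) for k in range(1, 16)} | {round(0.1 * k, 2) for k in range(1, 11)})
)

_CONFIG_SEED_STRIDE = 100_000


@dataclass(frozen=True)
class ExperimentPreset:
    """The full parameter grid of one canonical experiment."""

    name: str
    E_T: float = 20.0
    M_b: float = 0.05
    C_p: float = 0.01
    C_m: float = 0.02
    E_s: float = 2.0
    grid_side: int = 41
    initial_energy: float = 2.0
    n_steps: int = 500
    replicates: int = 30
    strategies: tuple[str, ...] = STRATEGIES
    heuristics: tuple[str, ...] = ("repetition",)
    levels: tuple[float, ...] = (5, 6, 15, 55, 105)
    p_g_grid: tuple[float, ...] = EXP1_PG_GRID
    seasonal: bool = False
    t_ab: float = 60.0
    t_fam: float = 40.0
    stds: tuple[float, ...] = (0.0,)
    n_cycles: int = 10
    initial_populations: tuple[int, ...] = (1680,)


EXP1 = ExperimentPreset(name="exp1")
EXP2 = ExperimentPreset(
    name="exp2", E_s=3.0, n_steps=1000, levels=(55, 105), p_g_grid=(0.0, 1.0),
    seasonal=True, stds=(0.0, 1.0, 5.0), heuristics=HEURISTICS,
)
EXP3 = ExperimentPreset(
    name="exp3", E_s=3.0, n_steps=1000, levels=(55, 105), p_g_grid=(0.0, 1.0),
    seasonal=True, stds=(0.0,), heuristics=HEURISTICS, strategies=("FF",),
    initial_populations=(1680, 1260, 840, 420),
)


def _params(preset: ExperimentPreset, seed: int, e_s: float | None = None) -> SimulationParams:
    return SimulationParams(
        seed=seed,
        grid_side=preset.grid_side,
        E_T=preset.E_T,
        M_b=preset.M_b,
        C_p=preset.C_p,
        C_m=preset.C_m,
        E_s=preset.E_s if e_s is None else e_s,
        initial_energy=preset.initial_energy,
        n_steps=preset.n_steps,
        replicate_count=preset.replicates,
    )


def exp1_config(
    strategy: str,
    high_level: float,
    p_g: float,
    seed: int,
    count_per_group: int = 840,
    n_steps: int = 500,
) -> RunConfig:
    """One experiment-1 cell: level 5 vs ``high_level`` at constant ``p_g``."""
    params = replace(_params(EXP1, seed), n_steps=n_steps)
    return RunConfig(
        params=params,
        schedule=FoodSchedule(mode="constant", p_g=p_g),
        population=[
            PopulationGroup(count_per_group, 5.0, strategy, "repetition"),
            PopulationGroup(count_per_group, float(high_level), strategy, "repetition"),
        ],
    )


def exp2_config(
    strategy: str = "FF",
    heuristic: str = "repetition",
    std: float = 0.0,
    seed: int = 0,
    total_population: int = 1680,
) -> RunConfig:
    """One experiment-2 cell: levels 55/105 in a 60/40 feast-famine schedule."""
    half = total_population // 2
    return RunConfig(
        params=_params(EXP2, seed),
        schedule=FoodSchedule(mode="seasonal", t_ab=EXP2.t_ab, t_fam=EXP2.t_fam,
                              std=std, n_cycles=EXP2.n_cycles),
        population=[
            PopulationGroup(half, 55.0, strategy, heuristic),
            PopulationGroup(total_population - half, 105.0, strategy, heuristic),
        ],
    )


def exp3_config(heuristic: str, total_population: int, seed: int = 0) -> RunConfig:
    """One experiment-3 cell: exp2's FF setting at a reduced initial density."""
    return exp2_config("FF", heuristic, std=0.0, seed=seed, total_population=total_population)


@dataclass
class Ensemble:
    """Replicate set of one configuration with per-replicate summaries."""

    config: RunConfig
    seeds: list[int]
    cycles: pd.DataFrame | None          # per-replicate cycle summaries
    finals: pd.DataFrame                 # per-replicate final-step populations
    steps: pd.DataFrame | None = None    # per-replicate step records (optional)

    def final_counts(self, level: float, strategy: str | None = None) -> np.ndarray:
        """Per-replicate living count of ``level`` agents at the final step."""
        df = self.finals[self.finals["level"] == level]
        if strategy is not None:
            df = df[df["strategy"] == strategy]
        return df.groupby("replicate")["population"].sum().to_numpy()

    def cycle_mean_population(self, cycle: int, level: float) -> np.ndarray:
        """Per-replicate mean population of ``level`` over the steps of ``cycle``."""
        df = self.cycles
        sel = df[(df["cycle"] == cycle) & (df["level"] == level)]
        return sel.groupby("replicate")["mean_population"].sum().to_numpy()

    def cycle_mean_energy(self, cycle: int, level: float, empty_as_zero: bool = True) -> np.ndarray:
        """Per-replicate mean energy of ``level`` agents over the steps of ``cycle``.

        With ``empty_as_zero`` (the convention of per-cycle energy curves),
        steps on which the group is extinct contribute zero energy; otherwise
        they are skipped and a fully extinct replicate yields NaN.
        """
        df = self.cycles
        sel = df[(df["cycle"] == cycle) & (df["level"] == level)]
        col = "mean_energy_filled" if empty_as_zero else "mean_energy"
        return sel.groupby("replicate")[col].mean().to_numpy()


def run_ensemble(
    config: RunConfig,
    replicates: int | None = None,
    master_seed: int | None = None,
    keep_steps: bool = False,
) -> Ensemble:
    """Run ``replicates`` independent seeded replicates of ``config``.

    Replicate ``r`` uses seed ``master_seed + r`` (master defaults to the
    config's own seed), making every replicate independently re-runnable.
    """
    config.validate()
    n_rep = replicates if replicates is not None else config.params.replicate_count
    master = master_seed if master_seed is not None else config.params.seed
    seeds = [master + r for r in range(n_rep)]

    cyc_frames, fin_frames, step_frames = [], [], []
    for r, seed in enumerate(seeds):
        res = run_simulation(config, seed=seed)
        last = res.steps[res.steps["step"] == res.steps["step"].max()].copy()
        last["replicate"] = r
        fin_frames.append(last)
        if res.cycles is not None:
            c = res.cycles.copy()
            c["replicate"] = r
            cyc_frames.append(c)
        if keep_steps:
            s = res.steps.copy()
            s["replicate"] = r
            step_frames.append(s)

    return Ensemble(
        config=config,
        seeds=seeds,
        cycles=pd.concat(cyc_frames, ignore_index=True) if cyc_frames else None,
        finals=pd.concat(fin_frames, ignore_index=True),
        steps=pd.concat(step_frames, ignore_index=True) if step_frames else None,
    )


def run_exp1(
    master_seed: int,
    strategies: tuple[str, ...] = EXP1.strategies,
    high_levels: tuple[float, ...] = (6, 15, 55, 105),
    p_gs: tuple[float, ...] = EXP1_PG_GRID,
    replicates: int = EXP1.replicates,
    n_steps: int = EXP1.n_steps,
) -> pd.DataFrame:
    """Survivor-difference table of experiment 1.

    Returns one row per (strategy, high_level, p_g, replicate) with the
    final-step populations of both level groups and their difference
    (high minus 5).
    """
    rows = []
    cfg_ix = 0
    for strategy in strategies:
        for level in high_levels:
            for p_g in p_gs:
                base = master_seed + _CONFIG_SEED_STRIDE * cfg_ix
                cfg_ix += 1
                cfg = exp1_config(strategy, level, p_g, seed=base, n_steps=n_steps)
                ens = run_ensemble(cfg, replicates=replicates, master_seed=base)
                low = ens.final_counts(5.0)
                high = ens.final_counts(float(level))
                for r in range(replicates):
                    rows.append(
                        {
                            "strategy": strategy, "high_level": level, "p_g": p_g,
                            "replicate": r, "pop_low": int(low[r]), "pop_high": int(high[r]),
                            "difference": int(high[r] - low[r]),
                        }
                    )
    return pd.DataFrame(rows)


def run_exp2(
    master_seed: int,
    strategies: tuple[str, ...] = ("FF",),
    heuristics: tuple[str, ...] = HEURISTICS,
    stds: tuple[float, ...] = (0.0,),
    replicates: int = EXP2.replicates,
    keep_steps: bool = False,
) -> dict[tuple[str, str, float], Ensemble]:
    """Experiment-2 sweep; returns ensembles keyed by (strategy, heuristic, std)."""
    out: dict[tuple[str, str, float], Ensemble] = {}
    cfg_ix = 0
    for strategy in strategies:
        for heuristic in heuristics:
            for std in stds:
                base = master_seed + _CONFIG_SEED_STRIDE * cfg_ix
                cfg_ix += 1
                cfg = exp2_config(strategy, heuristic, std, seed=base)
                out[(strategy, heuristic, std)] = run_ensemble(
                    cfg, replicates=replicates, master_seed=base, keep_steps=keep_steps
                )
    return out


def run_exp3(
    master_seed: int,
    heuristics: tuple[str, ...] = HEURISTICS,
    initial_populations: tuple[int, ...] = EXP3.initial_populations,
    replicates: int = EXP3.replicates,
) -> dict[tuple[str, int], Ensemble]:
    """Experiment-3 sweep; returns ensembles keyed by (heuristic, initial population)."""
    out: dict[tuple[str, int], Ensemble] = {}
    cfg_ix = 0
    for heuristic in heuristics:
        for total in initial_populations:
            base = master_seed + _CONFIG_SEED_STRIDE * cfg_ix
            cfg_ix += 1
            cfg = exp3_config(heuristic, total, seed=base)
            out[(heuristic, total)] = run_ensemble(cfg, replicates=replicates, master_seed=base)
    return out
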