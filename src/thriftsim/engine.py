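"""The per-step scheduler binding environment, agents and heuristics.

The engine keeps the population as flat numpy arrays (one entry per living
agent) and executes each step in six phases:

1. shuffle the living agents into a fresh uniform processing order;
2. every agent, in that order, eats, perceives and moves -- contention for a
   cell's portion is resolved in favor of the earlier agent, and a later
   agent's perception sees the grid as already depleted by earlier eaters
   (this sequential semantics is reproduced exactly in array form via
   per-cell first-eater ranks and per-cell consumption chains);
3. perception cost and basal expenditure are charged and starvation deaths
   resolved (basal is assessed on start-of-turn energy, see ``agents``);
4. the surviving agents apply their decision heuristic synchronously, using
   end-of-step energies and positions; an agent that adopts a storage ceiling
   below its current energy keeps that energy but cannot eat until basal
   expenditure has brought it back under the ceiling;
5. cells still empty after the actions regenerate once for the next time
   unit, with that unit's probability ``p_g(t+1)``;
6. a per-step record is emitted (populations counted after deaths; food count
   after regeneration).

Regeneration is *immediate*: a portion consumed during step ``t`` reappears
within the same step with probability ``p_g(t)``, available to agents acting
later in the processing order.  Under full abundance (p_g = 1) food is
therefore continuously available -- portions are replaced the moment they are
eaten and cell-sharing agents do not compete -- while under total famine
(p_g = 0) consumption is final and the single portion per cell goes to the
earliest agent.  Together with the boundary regeneration in phase 5 this
makes a famine of length ``t_fam`` deprive agents of regeneration for exactly
``t_fam`` steps: the last abundance step still replaces what was eaten, and
the first abundance step finds a replenished grid.

Every run also produces a per-step energy audit (portions eaten, truncation
waste, movement/perception/basal costs, energy removed by deaths) that closes
the books to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agents import movement_probability
from .config import HEURISTICS, STRATEGIES, FoodSchedule, PopulationGroup, RunConfig, SimulationParams
from .environment import RealizedSchedule, build_schedule, neighbor_table

__all__ = ["Population", "Simulation", "SimulationResult", "initialize_population", "run_simulation"]

_STRAT_CODE = {s: i for i, s in enumerate(STRATEGIES)}
_HEUR_CODE = {h: i for i, h in enumerate(HEURISTICS)}


@dataclass
class Population:
    """Struct-of-arrays population state (living agents only)."""

    cell: np.ndarray     # int64 flat cell id
    energy: np.ndarray   # float64
    level: np.ndarray    # float64 storage ceiling
    strat: np.ndarray    # int8 code into STRATEGIES
    heur: np.ndarray     # int8 code into HEURISTICS

    def __len__(self) -> int:
        return self.cell.size


def initialize_population(
    groups: list[PopulationGroup],
    grid_side: int,
    initial_energy: float,
    rng: np.random.Generator,
) -> Population:
    """Spread the initial agents randomly over the grid, at most one per cell.

    Agents are assigned to cells drawn uniformly without replacement, giving
    an approximately uniform density of ``total / grid_side**2`` agents per
    cell (the canonical configurations use at most one agent per cell).  If
    the population exceeds the number of cells, the excess agents are placed
    uniformly at random on top.  Multiple occupancy arises freely later
    through movement.  Group counts are honored exactly; zero-count groups
    contribute nothing.
    """
    groups = [g for g in groups if g.count > 0]
    total = sum(g.count for g in groups)
    if total <= 0:
        raise ValueError("total initial population must be > 0")
    n_cells = grid_side * grid_side
    if total <= n_cells:
        cell = rng.permutation(n_cells)[:total]
    else:
        cell = np.concatenate(
            [rng.permutation(n_cells), rng.integers(0, n_cells, size=total - n_cells)]
        )
        cell = cell[rng.permutation(total)]
    level = np.concatenate([np.full(g.count, float(g.level)) for g in groups])
    strat = np.concatenate([np.full(g.count, _STRAT_CODE[g.strategy], dtype=np.int8) for g in groups])
    heur = np.concatenate([np.full(g.count, _HEUR_CODE[g.heuristic], dtype=np.int8) for g in groups])
    if initial_energy > level.min():
        raise ValueError("initial_energy exceeds the smallest accumulation level")
    return Population(
        cell=cell.astype(np.int64),
        energy=np.full(total, float(initial_energy)),
        level=level,
        strat=strat,
        heur=heur,
    )


@dataclass
class SimulationResult:
    """Outputs of one run: per-step records, per-cycle summaries, audit trail."""

    steps: pd.DataFrame          # step, phase, strategy, level, heuristic, population, mean_energy, food_cells
    cycles: pd.DataFrame | None  # cycle, strategy, level, heuristic, mean_population, mean_energy
    audit: pd.DataFrame
    schedule: RealizedSchedule
    params: SimulationParams

    def final_counts(self) -> pd.Series:
        """Living population by (strategy, level, heuristic) at the last recorded step."""
        last = self.steps[self.steps["step"] == self.steps["step"].max()]
        return last.set_index(["strategy", "level", "heuristic"])["population"]


class Simulation:
    """One seeded realization of the agent-based model."""

    def __init__(
        self,
        params: SimulationParams,
        schedule: FoodSchedule | RealizedSchedule,
        population: list[PopulationGroup] | Population,
        rng: np.random.Generator | None = None,
        initial_food: bool = True,
    ):
        params.validate()
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)

        if isinstance(schedule, RealizedSchedule):
            self.schedule = schedule
        else:
            # +1 so the boundary regeneration of the final step is well defined
            min_steps = None if params.n_steps is None else params.n_steps + 1
            self.schedule = build_schedule(schedule, self.rng, min_steps=min_steps)

        side = params.grid_side
        self._ncells = side * side
        self._nbr = neighbor_table(side)
        # all cells start food-bearing: seasonal runs open in abundance and
        # constant-p_g runs equilibrate quickly (logged, configurable).
        self.food = np.full(self._ncells, bool(initial_food))

        if isinstance(population, Population):
            self.pop = population
        else:
            self.pop = initialize_population(population, side, params.initial_energy, self.rng)

        # record-group bookkeeping: (strategy, heuristic) pairs are fixed per
        # agent; levels move within the initial level set, so groups are the
        # cartesian product of observed pairs and levels.
        self._ulevels = np.unique(self.pop.level)
        pairs = sorted({(int(s), int(h)) for s, h in zip(self.pop.strat, self.pop.heur)})
        self._pair_index = -np.ones((len(STRATEGIES), len(HEURISTICS)), dtype=np.int64)
        for i, (s, h) in enumerate(pairs):
            self._pair_index[s, h] = i
        self._pairs = pairs
        self._n_groups = len(pairs) * self._ulevels.size

        self._t = 0
        self._records: list[tuple] = []   # (step, phase, pops, esum, food_count)
        self._audit_rows: list[dict] = []

    # ------------------------------------------------------------------ #

    def _group_codes(self) -> np.ndarray:
        li = np.searchsorted(self._ulevels, self.pop.level)
        return self._pair_index[self.pop.strat, self.pop.heur] * self._ulevels.size + li

    def _record(self, step: int) -> None:
        g = self._group_codes()
        pops = np.bincount(g, minlength=self._n_groups)
        esum = np.bincount(g, weights=self.pop.energy, minlength=self._n_groups)
        self._records.append((step, self.schedule.phase(step), pops, esum, int(self.food.sum())))

    # ------------------------------------------------------------------ #

    def step(self) -> None:
        """Advance the simulation by one time step (phases 1-6)."""
        t = self._t
        p_g = self.schedule.p_g(t)
        pop = self.pop
        rng = self.rng
        pr = self.params
        n = len(pop)

        audit = {
            "step": t, "eaten": 0, "waste": 0.0, "move_cost": 0.0,
            "percep_cost": 0.0, "basal": 0.0, "death_loss": 0.0,
            "energy_before": float(pop.energy.sum()),
        }

        if n > 0:
            # -- phase 1: fresh uniform processing order ------------------ #
            order = rng.permutation(n)
            rank = np.empty(n, dtype=np.int64)
            rank[order] = np.arange(n)

            e_start = pop.energy.copy()
            grid0 = self.food.copy()

            # -- phase 2a: eating with first-come contention and immediate
            #    regeneration.  Candidates on a food-bearing cell consume in
            #    rank order; after each consumption the portion reappears at
            #    once with probability p_g, feeding the next candidate too.
            cand = grid0[pop.cell] & (pop.energy < pop.level)
            ate = np.zeros(n, dtype=bool)
            cidx = np.flatnonzero(cand)
            if cidx.size:
                srt = cidx[np.lexsort((rank[cidx], pop.cell[cidx]))]
                c_sorted = pop.cell[srt]
                is_first = np.empty(c_sorted.size, dtype=bool)
                is_first[0] = True
                is_first[1:] = c_sorted[1:] != c_sorted[:-1]
                regen_ok = rng.random(srt.size) < p_g
                # candidate j of a cell eats iff no regeneration failure among
                # the earlier candidates of the same cell (prefix of successes)
                fails_before = np.r_[0, np.cumsum(~regen_ok)[:-1]]
                block_base = fails_before[is_first][np.cumsum(is_first) - 1]
                eats_sorted = (fails_before - block_base) == 0
                ate[srt[eats_sorted]] = True
                # cell state after its last consumption's regeneration draw
                block_id = np.cumsum(is_first) - 1
                n_blocks = int(is_first.sum())
                last_eat_pos = np.zeros(n_blocks, dtype=np.int64)
                np.maximum.at(last_eat_pos, block_id[eats_sorted],
                              np.flatnonzero(eats_sorted))
                self.food[c_sorted[is_first]] = regen_ok[last_eat_pos]

            eater_rank = np.full(self._ncells, n, dtype=np.int64)
            np.minimum.at(eater_rank, pop.cell[ate], rank[ate])
            new_e = np.minimum(pop.energy[ate] + pr.E_s, pop.level[ate])
            audit["eaten"] = int(ate.sum())
            audit["waste"] = float((pop.energy[ate] + pr.E_s - new_e).sum())
            pop.energy[ate] = new_e

            # -- phase 2b: perception (grid as seen at each agent's turn) - #
            # a cell is visible as food-bearing to the rank-r agent iff it
            # held food at step start and its first eater (if any) comes
            # later; portions regenerated mid-step become visible next step.
            own_had_food = ate | (grid0[pop.cell] & (eater_rank[pop.cell] >= rank))
            nbr = self._nbr[pop.cell]                                   # (n, 8)
            vis = grid0[nbr] & (eater_rank[nbr] > rank[:, None])
            n_food = vis.sum(axis=1)

            # -- phase 2c: movement --------------------------------------- #
            rand_col = rng.integers(0, 8, size=n)
            u_food = rng.random(n)
            k = np.minimum((u_food * n_food).astype(np.int64), np.maximum(n_food - 1, 0))
            # column of the k-th visible portion; clamped placeholder when none
            # is visible (such rows never move toward food).
            food_col = np.minimum((vis.cumsum(axis=1) <= k[:, None]).sum(axis=1), 7)

            is_rf = pop.strat == _STRAT_CODE["RF"]
            is_df = pop.strat == _STRAT_CODE["DF"]
            is_ff = pop.strat == _STRAT_CODE["FF"]
            col = np.where((is_df & (n_food > 0)) | is_ff, food_col, rand_col)
            wants_move = is_rf | is_df | (is_ff & ~own_had_food & (n_food > 0))

            p_move = movement_probability(pop.energy, pr.E_s, pr.E_T)
            moved = wants_move & (rng.random(n) < p_move)
            target = nbr[np.arange(n), col]
            pop.cell[moved] = target[moved]
            cost = pr.C_m * pop.energy[moved]
            audit["move_cost"] = float(cost.sum())
            pop.energy[moved] -= cost

            # -- phase 3: metabolism and death ---------------------------- #
            perceives = is_df | is_ff
            audit["percep_cost"] = float(pr.C_p * perceives.sum())
            pop.energy[perceives] -= pr.C_p
            basal = np.where(e_start > pr.E_T, pr.M_b * e_start, pr.M_b * pr.E_T)
            audit["basal"] = float(basal.sum())
            pop.energy -= basal

            dead = pop.energy <= 0.0
            audit["death_loss"] = float(pop.energy[dead].sum())
            if dead.any():
                keep = ~dead
                self.pop = pop = Population(
                    cell=pop.cell[keep], energy=pop.energy[keep], level=pop.level[keep],
                    strat=pop.strat[keep], heur=pop.heur[keep],
                )

            # -- phase 4: synchronous heuristic updates ------------------- #
            self._heuristic_phase()

        # -- phase 5: end-of-step regeneration of still-empty cells; the
        # draw stocks the next time unit and so uses its probability ------- #
        self.food |= rng.random(self._ncells) < self.schedule.p_g(t + 1)

        # -- phase 6: record ----------------------------------------------- #
        audit["energy_after"] = float(self.pop.energy.sum())
        self._audit_rows.append(audit)
        self._record(t)
        self._t += 1

    # ------------------------------------------------------------------ #

    def _heuristic_phase(self) -> None:
        """Synchronous level adoption over survivors."""
        pop = self.pop
        n = len(pop)
        if n == 0 or not (pop.heur != _HEUR_CODE["repetition"]).any():
            return
        rng = self.rng
        cell, energy, level = pop.cell, pop.energy, pop.level
        ncells = self._ncells

        # agents sorted by (cell asc, energy desc): each cell's occupants form
        # a contiguous block whose first entries are its maximum-energy agents.
        order = np.lexsort((-energy, cell))
        cnt = np.bincount(cell, minlength=ncells)
        start = np.zeros(ncells + 1, dtype=np.int64)
        np.cumsum(cnt, out=start[1:])
        cell_max = np.full(ncells, -np.inf)
        np.maximum.at(cell_max, cell, energy)
        cnt_max = np.bincount(cell[energy == cell_max[cell]], minlength=ncells)

        perceives = (pop.strat == _STRAT_CODE["DF"]) | (pop.strat == _STRAT_CODE["FF"])
        comm = np.concatenate([cell[:, None], self._nbr[cell]], axis=1)   # (n, 9)
        active = np.ones((n, 9), dtype=bool)
        active[~perceives, 1:] = False   # non-perceivers see only their own cell

        new_level = level.copy()

        def _select(rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
            """Uniform draw over the (weighted-count) community members of each row.

            ``weights[i, j]`` is how many eligible members sit in community
            column ``j`` of row ``i``; eligible members occupy the first
            ``weights`` slots of each cell block in ``order``.
            """
            tot = weights.sum(axis=1)
            u = rng.random(rows.size)
            kk = np.minimum((u * tot).astype(np.int64), tot - 1)
            csum = weights.cumsum(axis=1)
            colsel = (csum <= kk[:, None]).sum(axis=1)
            r = np.arange(rows.size)
            within = kk - (csum[r, colsel] - weights[r, colsel])
            cells_sel = comm[rows, colsel]
            return level[order[start[cells_sel] + within]]

        imi = pop.heur == _HEUR_CODE["imitation"]
        if imi.any():
            rows = np.flatnonzero(imi)
            weights = np.where(active[rows], cnt[comm[rows]], 0)
            new_level[rows] = _select(rows, weights)

        inq = pop.heur == _HEUR_CODE["inquiring"]
        if inq.any():
            rows = np.flatnonzero(inq)
            cm = np.where(active[rows], cell_max[comm[rows]], -np.inf)
            best = cm.max(axis=1)
            weights = np.where(cm == best[:, None], cnt_max[comm[rows]], 0)
            new_level[rows] = _select(rows, weights)

        # adopting a smaller ceiling leaves energy untouched: the agent simply
        # cannot eat until its energy has decayed below the new level.
        pop.level = new_level

    # ------------------------------------------------------------------ #

    def run(self) -> SimulationResult:
        """Execute the configured number of steps and assemble the outputs."""
        n_steps = self.params.n_steps
        if n_steps is None:
            n_steps = self.schedule.total_steps
            if n_steps is None:
                raise ValueError("constant-p_g runs need an explicit n_steps")
        if n_steps == 0:
            self._record(0)   # initial-state snapshot only
        for _ in range(n_steps):
            self.step()
        return self._build_result(n_steps)

    def _build_result(self, n_steps: int) -> SimulationResult:
        nl = self._ulevels.size
        strat_names = np.array([STRATEGIES[s] for s, _ in self._pairs]).repeat(nl)
        heur_names = np.array([HEURISTICS[h] for _, h in self._pairs]).repeat(nl)
        level_vals = np.tile(self._ulevels, len(self._pairs))
        g = self._n_groups

        step_ix = np.array([r[0] for r in self._records])
        phases = np.array([r[1] for r in self._records], dtype=object)
        pops = np.vstack([r[2] for r in self._records])          # (T, G)
        esum = np.vstack([r[3] for r in self._records])
        food = np.array([r[4] for r in self._records])
        n_rec = step_ix.size
        mean_e = np.where(pops > 0, esum / np.maximum(pops, 1), np.nan)

        steps = pd.DataFrame(
            {
                "step": np.repeat(step_ix, g),
                "phase": np.repeat(phases, g),
                "strategy": np.tile(strat_names, n_rec),
                "level": np.tile(level_vals, n_rec),
                "heuristic": np.tile(heur_names, n_rec),
                "population": pops.ravel(),
                "mean_energy": mean_e.ravel(),
                "food_cells": np.repeat(food, g),
            }
        )

        cycles = None
        if self.schedule.mode == "seasonal":
            cycle_of_step = np.array([self.schedule.cycle(int(s)) for s in step_ix])
            cyc = steps.copy()
            cyc["cycle"] = np.repeat(cycle_of_step, g)
            # mean_energy skips steps where the group is extinct; the _filled
            # variant counts such steps as zero (an extinct population holds
            # no energy), which is the convention of per-cycle energy curves.
            cyc["mean_energy_filled"] = np.nan_to_num(cyc["mean_energy"].to_numpy())
            cycles = (
                cyc.groupby(["cycle", "strategy", "level", "heuristic"], as_index=False)
                .agg(
                    mean_population=("population", "mean"),
                    mean_energy=("mean_energy", "mean"),
                    mean_energy_filled=("mean_energy_filled", "mean"),
                )
            )
        audit = pd.DataFrame(self._audit_rows)
        return SimulationResult(
            steps=steps, cycles=cycles, audit=audit,
            schedule=self.schedule, params=self.params,
        )


def run_simulation(config: RunConfig, seed: int | None = None) -> SimulationResult:
    """Run one replicate of ``config`` (``seed`` overrides the configured one)."""
    config.validate()
    params = config.params
    if seed is not None:
        params = replace(params, seed=seed)
    sim = Simulation(params, config.schedule, config.population)
    return sim.run()
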