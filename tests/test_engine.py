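"""Engine scheduling: contention, determinism, oracle equivalence, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from thriftsim import (
    EnergyBudget,
    FoodSchedule,
    PopulationGroup,
    SimulationParams,
    time_to_starve,
    trajectory,
)
from thriftsim.engine import Population, Simulation, initialize_population, run_simulation
from thriftsim.config import RunConfig


def isolated_agent_sim(p_g, initial_energy, level=1e6, n_steps=200, initial_food=True, e_s=3.0):
    params = SimulationParams(seed=5, grid_side=5, E_s=e_s,
                              initial_energy=initial_energy, n_steps=n_steps)
    return Simulation(
        params,
        FoodSchedule(mode="constant", p_g=p_g),
        [PopulationGroup(1, level, "S", "repetition")],
        initial_food=initial_food,
    )


class TestOracleEquivalence:
    def test_feeding_sedentary_agent_tracks_closed_form(self):
        """With food every step, the engine reproduces the analytic trajectory."""
        sim = isolated_agent_sim(p_g=1.0, initial_energy=20.0)
        budget = EnergyBudget(3.0, 0.05, 20.0)
        for t in range(1, 201):
            sim.step()
            assert sim.pop.energy[0] == pytest.approx(trajectory(budget, t), abs=1e-9)

    def test_starving_sedentary_agent_dies_when_predicted(self):
        sim = isolated_agent_sim(p_g=0.0, initial_energy=55.0, level=105.0,
                                 initial_food=False, n_steps=100)
        steps = 0
        while len(sim.pop) and steps < 100:
            sim.step()
            steps += 1
        predicted = time_to_starve(EnergyBudget(3.0, 0.05, 20.0), 55.0)
        assert abs(steps - predicted) <= 1.0


class TestContention:
    def test_single_portion_feeds_exactly_one_agent_in_famine(self):
        params = SimulationParams(seed=2, grid_side=5, E_s=2.0, initial_energy=10.0, n_steps=1)
        pop = Population(
            cell=np.array([0, 0]),
            energy=np.array([10.0, 10.0]),
            level=np.array([55.0, 55.0]),
            strat=np.zeros(2, dtype=np.int8),
            heur=np.zeros(2, dtype=np.int8),
        )
        sim = Simulation(params, FoodSchedule(mode="constant", p_g=0.0), pop, initial_food=False)
        sim.food[0] = True
        sim.step()
        # winner: 10 + 2 - 1 = 11; loser: 10 - 1 = 9
        assert sorted(sim.pop.energy.tolist()) == pytest.approx([9.0, 11.0])
        assert not sim.food[0]

    def test_full_abundance_feeds_every_cellmate(self):
        """Immediate regeneration removes competition when p_g = 1."""
        params = SimulationParams(seed=2, grid_side=5, E_s=2.0, initial_energy=10.0, n_steps=1)
        pop = Population(
            cell=np.array([0, 0, 0]),
            energy=np.full(3, 10.0),
            level=np.full(3, 55.0),
            strat=np.zeros(3, dtype=np.int8),
            heur=np.zeros(3, dtype=np.int8),
        )
        sim = Simulation(params, FoodSchedule(mode="constant", p_g=1.0), pop)
        sim.step()
        assert sim.pop.energy.tolist() == pytest.approx([11.0, 11.0, 11.0])


class TestDeterminism:
    def make_config(self, seed=9):
        return RunConfig(
            params=SimulationParams(seed=seed, grid_side=11, E_s=3.0, n_steps=120),
            schedule=FoodSchedule(mode="seasonal", t_ab=12, t_fam=8, std=1.0, n_cycles=6),
            population=[
                PopulationGroup(30, 55.0, "FF", "imitation"),
                PopulationGroup(30, 105.0, "FF", "imitation"),
                PopulationGroup(20, 55.0, "RF", "repetition"),
                PopulationGroup(20, 105.0, "DF", "inquiring"),
            ],
        )

    def test_same_seed_bit_identical_records(self):
        a = run_simulation(self.make_config())
        b = run_simulation(self.make_config())
        pd.testing.assert_frame_equal(a.steps, b.steps)
        pd.testing.assert_frame_equal(a.audit, b.audit)

    def test_different_seeds_differ(self):
        a = run_simulation(self.make_config(seed=9))
        b = run_simulation(self.make_config(seed=10))
        assert not a.steps.equals(b.steps)


@pytest.fixture(scope="module")
def mixed_run():
    """A seasonal run with all strategies, repetition only (levels immutable)."""
    params = SimulationParams(seed=21, grid_side=13, E_s=3.0, n_steps=150)
    sim = Simulation(
        params,
        FoodSchedule(mode="seasonal", t_ab=15, t_fam=10, std=0.0, n_cycles=6),
        [PopulationGroup(40, 55.0, s, "repetition") for s in ("S", "RF", "DF", "FF")]
        + [PopulationGroup(40, 105.0, s, "repetition") for s in ("S", "RF", "DF", "FF")],
    )
    trace = []
    for _ in range(150):
        sim.step()
        trace.append(
            (len(sim.pop), sim.pop.energy.copy(), sim.pop.level.copy(), int(sim.food.sum()))
        )
    return sim, trace


class TestStepInvariants:
    def test_population_monotone_non_increasing(self, mixed_run):
        counts = [t[0] for t in mixed_run[1]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_living_energy_positive_and_within_storage_ceiling(self, mixed_run):
        for _, energy, level, _ in mixed_run[1]:
            assert (energy > 0).all()
            assert (energy <= level + 1e-9).all()

    def test_food_count_bounded_by_grid(self, mixed_run):
        sim, trace = mixed_run
        assert all(0 <= f <= sim._ncells for *_, f in trace)

    def test_energy_audit_closes(self, mixed_run):
        """Per-step energy book-keeping balances to floating-point accuracy."""
        sim, _ = mixed_run
        audit = pd.DataFrame(sim._audit_rows)
        delta = audit["energy_after"] - audit["energy_before"]
        rhs = (
            audit["eaten"] * sim.params.E_s
            - audit["waste"] - audit["move_cost"] - audit["percep_cost"]
            - audit["basal"] - audit["death_loss"]
        )
        assert np.allclose(delta, rhs, atol=1e-8)


class TestRunShapes:
    def test_seasonal_run_emits_one_record_per_step_and_cycle_summaries(self):
        cfg = RunConfig(
            params=SimulationParams(seed=3, grid_side=9, E_s=3.0, n_steps=None),
            schedule=FoodSchedule(mode="seasonal", t_ab=6, t_fam=4, std=0.0, n_cycles=3),
            population=[PopulationGroup(20, 55.0, "FF", "repetition")],
        )
        res = run_simulation(cfg)
        assert res.steps["step"].nunique() == 30
        assert sorted(res.cycles["cycle"].unique()) == [1, 2, 3]

    def test_constant_run_has_no_cycles(self):
        cfg = RunConfig(
            params=SimulationParams(seed=3, grid_side=9, n_steps=50),
            schedule=FoodSchedule(mode="constant", p_g=0.5),
            population=[PopulationGroup(20, 55.0, "S", "repetition")],
        )
        res = run_simulation(cfg)
        assert res.steps["step"].nunique() == 50
        assert res.cycles is None

    def test_zero_steps_snapshots_initial_state(self):
        cfg = RunConfig(
            params=SimulationParams(seed=3, grid_side=9, n_steps=0),
            schedule=FoodSchedule(mode="constant", p_g=0.5),
            population=[PopulationGroup(7, 55.0, "S", "repetition")],
        )
        res = run_simulation(cfg)
        assert res.steps["step"].nunique() == 1
        assert res.steps["population"].sum() == 7

    def test_total_extinction_is_absorbing(self):
        cfg = RunConfig(
            params=SimulationParams(seed=3, grid_side=9, E_s=2.0, initial_energy=2.0, n_steps=60),
            schedule=FoodSchedule(mode="constant", p_g=0.0),
            population=[PopulationGroup(15, 55.0, "S", "repetition")],
        )
        res = run_simulation(cfg)
        last = res.steps[res.steps["step"] == 59]
        assert last["population"].sum() == 0
        assert res.steps["step"].nunique() == 60

    def test_group_populations_sum_to_living_total(self):
        cfg = RunConfig(
            params=SimulationParams(seed=8, grid_side=11, E_s=3.0, n_steps=80),
            schedule=FoodSchedule(mode="seasonal", t_ab=10, t_fam=6, std=0.0, n_cycles=5),
            population=[PopulationGroup(25, 55.0, "FF", "imitation"),
                        PopulationGroup(25, 105.0, "FF", "imitation")],
        )
        sim = Simulation(cfg.params, cfg.schedule, cfg.population)
        for _ in range(80):
            sim.step()
            _, _, pops, _, _ = sim._records[-1]
            assert pops.sum() == len(sim.pop)


class TestInitialization:
    def test_group_counts_honored_and_energy_set(self, rng):
        groups = [PopulationGroup(10, 55.0, "S", "repetition"),
                  PopulationGroup(5, 105.0, "FF", "imitation")]
        pop = initialize_population(groups, 9, 2.0, rng)
        assert len(pop) == 15
        assert (pop.energy == 2.0).all()
        assert (pop.level == 55.0).sum() == 10

    def test_initial_spread_is_one_agent_per_cell(self, rng):
        groups = [PopulationGroup(80, 55.0, "S", "repetition")]
        pop = initialize_population(groups, 9, 2.0, rng)
        assert len(np.unique(pop.cell)) == 80

    def test_zero_count_group_absent_from_records(self):
        cfg = RunConfig(
            params=SimulationParams(seed=3, grid_side=9, n_steps=5),
            schedule=FoodSchedule(mode="constant", p_g=1.0),
            population=[PopulationGroup(10, 55.0, "S", "repetition"),
                        PopulationGroup(0, 105.0, "FF", "imitation")],
        )
        res = run_simulation(cfg)
        assert set(res.steps["strategy"].unique()) == {"S"}

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize_population([PopulationGroup(0, 55.0)], 9, 2.0, rng)

    def test_overflow_population_allowed(self, rng):
        pop = initialize_population([PopulationGroup(100, 55.0)], 9, 2.0, rng)
        assert len(pop) == 100   # 81 cells; multiple occupancy for the excess
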