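"""Per-agent metabolism and foraging behavior.

This module defines the reference (single-agent) semantics of one simulation
turn: the eat -> perceive -> move decision sequence, the energy-dependent
movement probability, the two-regime basal expenditure and starvation.  The
engine executes the same rules in array form over whole populations; these
scalar operations are the contract it is tested against.

Bookkeeping conventions (applied uniformly by engine and scalar path):

* a portion is consumed whole; intake beyond the accumulation level ``L`` is
  truncated (the level is a hard storage ceiling, and an agent only eats when
  ``energy < level``);
* movement probability is evaluated on post-consumption energy; the movement
  cost ``C_m * energy`` is charged only when the move is actually realized;
* perception (strategies DF and FF) costs ``C_p`` every turn, found food or
  not;
* basal expenditure is assessed on the energy the agent carried at the start
  of its turn (so that a feeding sedentary agent follows the closed-form
  accumulation law exactly, with stationary point ``E_s / M_b``) and deducted
  at the end of the step, after which an agent at energy <= 0 dies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .environment import FoodGrid

__all__ = [
    "AgentState",
    "ActionPlan",
    "movement_probability",
    "basal_expenditure",
    "plan_actions",
    "attempt_eat",
    "execute_move",
    "end_of_step_metabolism",
]

Cell = tuple[int, int]


@dataclass
class AgentState:
    """One agent: position, internal energy, storage ceiling, behavior, life."""

    agent_id: int
    row: int
    col: int
    energy: float
    level: float
    strategy: str = "S"
    heuristic: str = "repetition"
    alive: bool = True


@dataclass
class ActionPlan:
    """The per-turn decision vector. ``move_target=None`` means stay put."""

    wants_eat: bool
    wants_perceive: bool
    move_target: Cell | None


def movement_probability(energy, E_s: float, E_T: float):
    """Probability that a decided move is actually executed.

    Movement is uninhibited (p = 1) for energies in the band [E_s, E_T];
    outside it the probability decays exponentially -- depleted agents are too
    weak to move, heavy agents too encumbered:

        p = exp(energy - E_s)   if energy < E_s
        p = exp(E_T - energy)   if energy > E_T
        p = 1                   otherwise.

    Accepts scalars or arrays; the result lies in (0, 1].
    """
    e = np.asarray(energy, dtype=float)
    exponent = np.where(e < E_s, e - E_s, np.where(e > E_T, E_T - e, 0.0))
    p = np.exp(exponent)
    return float(p) if np.isscalar(energy) else p


def basal_expenditure(energy, M_b: float, E_T: float):
    """Mandatory per-step expenditure: ``M_b * energy`` above ``E_T``, else ``M_b * E_T``.

    The constant floor below threshold prevents agents from surviving
    indefinitely on an ever-shrinking metabolism; ``M_b * E_T`` is the minimum
    energy needed per step to stay alive.
    """
    e = np.asarray(energy, dtype=float)
    out = np.where(e > E_T, M_b * e, M_b * E_T)
    return float(out) if np.isscalar(energy) else out


def _pick(options: Sequence[Cell], rng: np.random.Generator) -> Cell:
    return options[int(rng.integers(len(options)))]


def plan_actions(
    agent: AgentState,
    own_cell_has_food: bool,
    perceived_neighbors: Mapping[Cell, bool] | None,
    rng: np.random.Generator,
    neighborhood: Sequence[Cell] | None = None,
) -> ActionPlan:
    """Build the decision vector for one turn of ``agent``.

    ``perceived_neighbors`` maps each Moore-neighbor cell to whether it holds
    food; it must be provided exactly for the perceiving strategies (DF, FF).
    ``neighborhood`` supplies the 8 neighbor cells for the non-perceiving
    mover RF (for DF/FF it defaults to the keys of the perception map).

    Strategy rules -- every strategy eats:

    * S   -- stay put.
    * RF  -- move to a uniformly random neighbor.
    * DF  -- move to a uniformly random food-bearing neighbor, or to a random
      neighbor anyway if none holds food.
    * FF  -- stay if the own cell had food this turn; otherwise move to a
      random food-bearing neighbor; if none, stay.
    """
    s = agent.strategy
    if s in ("DF", "FF"):
        if perceived_neighbors is None:
            raise ValueError(f"strategy {s} perceives: perceived_neighbors is required")
        if neighborhood is None:
            neighborhood = list(perceived_neighbors)
        food_cells = [c for c, has in perceived_neighbors.items() if has]
    elif perceived_neighbors is not None:
        raise ValueError(f"strategy {s} does not perceive")

    if s == "S":
        return ActionPlan(True, False, None)
    if s == "RF":
        if neighborhood is None:
            raise ValueError("RF needs the neighborhood to move into")
        return ActionPlan(True, False, _pick(list(neighborhood), rng))
    if s == "DF":
        target = _pick(food_cells, rng) if food_cells else _pick(list(neighborhood), rng)
        return ActionPlan(True, True, target)
    if s == "FF":
        if own_cell_has_food or not food_cells:
            return ActionPlan(True, True, None)
        return ActionPlan(True, True, _pick(food_cells, rng))
    raise ValueError(f"unknown strategy {s!r}")


def attempt_eat(agent: AgentState, grid: FoodGrid, E_s: float) -> bool:
    """Consume the portion in the agent's cell, if present and storable.

    The agent eats only while ``energy < level``; the portion is then removed
    whole and the intake truncated at the level (truncation excess is wasted).
    Returns whether the agent ate.
    """
    if grid.has_food[agent.row, agent.col] and agent.energy < agent.level:
        grid.has_food[agent.row, agent.col] = False
        agent.energy = min(agent.energy + E_s, agent.level)
        return True
    return False


def execute_move(
    agent: AgentState,
    plan: ActionPlan,
    E_s: float,
    E_T: float,
    C_m: float,
    rng: np.random.Generator,
) -> bool:
    """Resolve a planned move with the energy-dependent success probability.

    On success the agent relocates and pays ``C_m`` times its (pre-move)
    energy; a failed roll leaves position and energy untouched -- no mass
    moved, no cost.  Returns whether the agent moved.
    """
    if plan.move_target is None:
        return False
    p = movement_probability(agent.energy, E_s, E_T)
    if rng.random() < p:
        agent.row, agent.col = plan.move_target
        agent.energy -= C_m * agent.energy
        return True
    return False


def end_of_step_metabolism(
    agent: AgentState,
    perceived: bool,
    M_b: float,
    E_T: float,
    C_p: float,
    turn_start_energy: float | None = None,
) -> None:
    """Charge perception cost and basal expenditure; resolve starvation.

    Basal expenditure is assessed on ``turn_start_energy`` -- the energy the
    agent carried before this turn's consumption (defaults to the current
    energy, which is equivalent when nothing was eaten).  An agent whose
    energy drops to or below zero dies.
    """
    if turn_start_energy is None:
        turn_start_energy = agent.energy
    if perceived:
        agent.energy -= C_p
    agent.energy -= basal_expenditure(turn_start_energy, M_b, E_T)
    if agent.energy <= 0.0:
        agent.alive = False
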