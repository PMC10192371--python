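"""Social update of the energy accumulation level (CONSUMAT-style heuristics).

Once per step, after all actions, metabolism and deaths, every surviving agent
may revise its accumulation level by looking at its *community*: the living
agents in its own cell, extended to the 8 adjacent cells when the agent's
foraging strategy includes perception (DF, FF).  The focal agent is itself a
community member, so an agent alone in an empty neighborhood always keeps its
level.

Three rules are implemented:

* repetition -- keep the current level;
* imitation  -- adopt the level of a uniformly random community member;
* inquiring  -- adopt the level of the community member with the highest
  internal energy (ties broken uniformly at random).

Adopted levels are therefore always values already present in the community;
no novel level can arise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .agents import AgentState
from .environment import FoodGrid

__all__ = ["Community", "build_community", "apply_heuristic"]

Cell = tuple[int, int]


@dataclass
class Community:
    """The agents a focal agent can observe this step (itself included)."""

    focal_agent_id: int
    member_ids: list[int]
    member_energies: list[float]
    member_levels: list[float]

    def __post_init__(self) -> None:
        if self.focal_agent_id not in self.member_ids:
            raise ValueError("the focal agent must belong to its own community")


def build_community(
    focal: AgentState,
    occupancy: Mapping[Cell, Sequence[AgentState]],
    perceives: bool,
    grid: FoodGrid,
) -> Community:
    """Collect the community of ``focal`` from a cell -> living-agents index.

    Same-cell agents are always included; the 8 Moore-neighbor cells are added
    iff ``perceives`` (i.e. the focal strategy is DF or FF).
    """
    cells: list[Cell] = [(focal.row, focal.col)]
    if perceives:
        cells.extend(grid.neighbors(focal.row, focal.col))
    members = [a for c in cells for a in occupancy.get(c, ()) if a.alive]
    return Community(
        focal_agent_id=focal.agent_id,
        member_ids=[a.agent_id for a in members],
        member_energies=[a.energy for a in members],
        member_levels=[a.level for a in members],
    )


def apply_heuristic(
    focal: AgentState,
    community: Community,
    rng: np.random.Generator,
) -> float:
    """Return the accumulation level ``focal`` adopts for the next step."""
    h = focal.heuristic
    if h == "repetition":
        return focal.level
    if h == "imitation":
        k = int(rng.integers(len(community.member_ids)))
        return community.member_levels[k]
    if h == "inquiring":
        energies = np.asarray(community.member_energies)
        best = np.flatnonzero(energies == energies.max())
        k = int(best[rng.integers(best.size)])
        return community.member_levels[k]
    raise ValueError(f"unknown heuristic {h!r}")
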