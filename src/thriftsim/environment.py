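"""The food environment: a periodic square lattice plus a regeneration schedule.

Each cell of the ``side x side`` torus holds at most one food portion of fixed
energy ``E_s``.  Empty cells refill independently with probability ``p_g`` per
step; ``p_g`` is either constant or follows a realized feast-famine schedule
(abundance periods with p_g = 1 alternating with famine periods with p_g = 0,
lengths drawn from normal distributions).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import FoodSchedule

__all__ = ["FoodGrid", "neighbor_table", "build_schedule", "RealizedSchedule", "Period"]


@lru_cache(maxsize=None)
def neighbor_table(side: int) -> np.ndarray:
    """Flat-cell-id Moore neighborhoods under toroidal wrap-around.

    Returns an ``(side*side, 8)`` int array; row ``r*side + c`` lists the eight
    distinct neighbors of cell ``(r, c)`` (the center cell is excluded).
    Requires ``side >= 3`` so that all eight neighbors are distinct.
    """
    if side < 3:
        raise ValueError("side must be >= 3")
    rows, cols = np.divmod(np.arange(side * side), side)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    out = np.empty((side * side, 8), dtype=np.int64)
    for j, (dr, dc) in enumerate(offsets):
        out[:, j] = ((rows + dr) % side) * side + (cols + dc) % side
    out.setflags(write=False)
    return out


class FoodGrid:
    """Boolean food occupancy on a ``side x side`` torus (one portion per cell)."""

    def __init__(self, side: int, full: bool = True):
        if side < 3:
            raise ValueError("side must be >= 3")
        self.side = side
        self.has_food = np.full((side, side), bool(full))

    @property
    def n_cells(self) -> int:
        return self.side * self.side

    def food_count(self) -> int:
        return int(self.has_food.sum())

    def neighbors(self, row: int, col: int) -> list[tuple[int, int]]:
        """The 8 Moore neighbors of ``(row, col)`` under wrap-around."""
        if not (0 <= row < self.side and 0 <= col < self.side):
            raise ValueError("cell outside grid")
        cells = neighbor_table(self.side)[row * self.side + col]
        return [divmod(int(c), self.side) for c in cells]

    def regenerate(self, p_g: float, rng: np.random.Generator) -> None:
        """Refill each empty cell independently with probability ``p_g``.

        Food-bearing cells are left untouched (at most one portion per cell);
        regeneration never removes food.
        """
        if not 0.0 <= p_g <= 1.0:
            raise ValueError("p_g must lie in [0, 1]")
        draws = rng.random(self.has_food.shape)
        self.has_food |= draws < p_g


@dataclass(frozen=True)
class Period:
    """One realized schedule phase."""

    phase: str       # "abundance" | "famine" | "constant"
    length: int
    start: int
    cycle: int       # 1-based cycle index; 0 for constant mode


@dataclass
class RealizedSchedule:
    """A step-indexed regeneration probability function.

    For seasonal schedules the alternating period lengths are drawn once at
    run start and frozen here; ``p_g(t)``, ``phase(t)`` and ``cycle(t)`` are
    then pure lookups.  Constant mode is a single infinite phase.
    """

    mode: str
    periods: list[Period]
    constant_p_g: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "seasonal":
            self._p = np.concatenate(
                [np.full(p.length, 1.0 if p.phase == "abundance" else 0.0) for p in self.periods]
            )
            self._phase = np.concatenate(
                [np.full(p.length, 0 if p.phase == "abundance" else 1, dtype=np.int8)
                 for p in self.periods]
            )
            self._cycle = np.concatenate(
                [np.full(p.length, p.cycle, dtype=np.int32) for p in self.periods]
            )

    @property
    def total_steps(self) -> int | None:
        """Total realized length; None for the infinite constant phase."""
        return None if self.mode == "constant" else int(self._p.size)

    @property
    def n_cycles(self) -> int:
        return 0 if self.mode == "constant" else int(self.periods[-1].cycle)

    def p_g(self, t: int) -> float:
        if self.mode == "constant":
            return float(self.constant_p_g)
        return float(self._p[min(t, self._p.size - 1)])

    def phase(self, t: int) -> str:
        if self.mode == "constant":
            return "constant"
        return "abundance" if self._phase[t] == 0 else "famine"

    def cycle(self, t: int) -> int:
        """1-based cycle index of step ``t`` (0 in constant mode)."""
        if self.mode == "constant":
            return 0
        return int(self._cycle[t])

    def to_frame(self) -> pd.DataFrame:
        """Realized periods as a table (cycle, phase, length, start_step)."""
        return pd.DataFrame(
            {
                "cycle": [p.cycle for p in self.periods],
                "phase": [p.phase for p in self.periods],
                "length": [p.length for p in self.periods],
                "start_step": [p.start for p in self.periods],
            }
        )


def _draw_length(mean: float, std: float, rng: np.random.Generator) -> int:
    """One period length: N(mean, std) rounded to nearest int, clipped at 1."""
    return max(1, int(np.rint(rng.normal(mean, std))))


def build_schedule(
    schedule: FoodSchedule,
    rng: np.random.Generator,
    min_steps: int | None = None,
) -> RealizedSchedule:
    """Realize a :class:`FoodSchedule` into concrete periods.

    Seasonal mode draws ``n_cycles`` (abundance, famine) pairs, abundance
    first; if ``min_steps`` exceeds the realized total, further cycles are
    appended until the whole run is covered (relevant when period lengths are
    stochastic but the run length is fixed).
    """
    schedule.validate()
    if schedule.mode == "constant":
        return RealizedSchedule(
            mode="constant",
            periods=[Period("constant", 0, 0, 0)],
            constant_p_g=schedule.p_g,
        )

    periods: list[Period] = []
    start = 0
    cycle = 0
    while cycle < schedule.n_cycles or (min_steps is not None and start < min_steps):
        cycle += 1
        ab = _draw_length(schedule.t_ab, schedule.std, rng)
        periods.append(Period("abundance", ab, start, cycle))
        start += ab
        fam = _draw_length(schedule.t_fam, schedule.std, rng)
        periods.append(Period("famine", fam, start, cycle))
        start += fam
    return RealizedSchedule(mode="seasonal", periods=periods)
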