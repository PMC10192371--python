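"""Closed-form energy-budget mathematics for the cost-free sedentary agent.

An agent that eats one portion ``E_s`` every step and pays only basal
metabolism follows the discrete recursion

    E(t) = E(t-1) + E_s - M_b * E(t-1),      E(t) > E_T,

whose solution is the saturating trajectory

    E(t) = (E_s / M_b) * (1 - (1 - M_b)**t) + (1 - M_b)**t * E(0),

with fixed point ``E_max = E_s / M_b`` (consumption balances expenditure).
Below the threshold ``E_T`` the expenditure is the constant ``M_b * E_T``, so
the climb from zero to ``E_T`` takes ``E_T / (E_s - M_b * E_T)`` steps.

These closed forms answer the two questions that calibrate the feast-famine
schedule: how long must an abundance period last for an agent to reach a given
energy, and how long must a famine last to starve it.  They also serve as the
independent oracle for the simulation engine: an isolated sedentary agent must
track them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnergyBudget",
    "max_energy",
    "trajectory",
    "time_to_accumulate",
    "time_to_starve",
]


@dataclass(frozen=True)
class EnergyBudget:
    """Metabolic settings of a cost-free (sedentary, non-perceiving) agent.

    Parameters
    ----------
    E_s : float
        Energy gained per consumed food portion.
    M_b : float
        Base metabolic rate (fraction of body energy per step above ``E_T``).
    E_T : float
        Energy threshold below which expenditure is the constant ``M_b * E_T``.
    """

    E_s: float
    M_b: float
    E_T: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.M_b <= 1.0:
            raise ValueError("M_b must satisfy 0 < M_b <= 1")
        if self.E_s <= 0.0 or self.E_T <= 0.0:
            raise ValueError("E_s and E_T must be positive")
        if self.E_s <= self.M_b * self.E_T:
            raise ValueError(
                "need E_s > M_b * E_T, otherwise there is no net gain below "
                "threshold and the climb time from zero is undefined"
            )


def max_energy(budget: EnergyBudget) -> float:
    """Stationary energy ``E_s / M_b`` where consumption equals expenditure."""
    return budget.E_s / budget.M_b


def trajectory(budget: EnergyBudget, t: float, start_energy: float | None = None) -> float:
    """Energy after ``t`` steps of uninterrupted feeding, starting at or above ``E_T``.

    Fractional ``t`` is accepted (the geometric form interpolates smoothly
    between integer steps).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    e0 = budget.E_T if start_energy is None else start_energy
    if e0 < budget.E_T:
        raise ValueError("trajectory is only valid for start_energy >= E_T")
    q = (1.0 - budget.M_b) ** t
    return max_energy(budget) * (1.0 - q) + q * e0


def time_to_accumulate(budget: EnergyBudget, target: float, from_zero: bool = False) -> float:
    """Steps of uninterrupted feeding needed to reach ``target`` energy.

    The count starts at ``E_T`` (the geometric regime); with ``from_zero=True``
    the linear climb ``E_T / (E_s - M_b * E_T)`` from zero energy is added.
    Returns a real-valued (possibly fractional) step count.
    """
    if budget.M_b >= 1.0:
        raise ValueError("time_to_accumulate requires M_b < 1")
    e_max = max_energy(budget)
    if target >= e_max:
        raise ValueError(f"target {target} is unreachable (>= E_s/M_b = {e_max})")
    if target < budget.E_T:
        raise ValueError("target must be >= E_T")
    t = (math.log(e_max - target) - math.log(e_max - budget.E_T)) / math.log(1.0 - budget.M_b)
    if from_zero:
        t += budget.E_T / (budget.E_s - budget.M_b * budget.E_T)
    return t


def time_to_starve(budget: EnergyBudget, start_energy: float) -> float:
    """Steps of total famine needed to drive an agent from ``start_energy`` to zero.

    Above ``E_T`` energy decays geometrically; below it the constant drain
    ``M_b * E_T`` empties the remaining ``E_T`` units in ``1 / M_b`` steps.
    """
    if budget.M_b >= 1.0:
        raise ValueError("time_to_starve requires M_b < 1")
    if start_energy < budget.E_T:
        raise ValueError("start_energy must be >= E_T")
    return (math.log(budget.E_T) - math.log(start_energy)) / math.log(1.0 - budget.M_b) + 1.0 / budget.M_b
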