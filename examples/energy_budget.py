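"""Closed-form energy budget of a cost-free sedentary agent.

Computes the stationary energy maximum, the time to build a given energy
store under uninterrupted feeding, and the time to starve from it, for the
portion sizes used in the constant (E_s = 2) and seasonal (E_s = 3) food
environments.  These numbers calibrate the 60-step abundance / 40-step
famine cycle: an agent can just build a 55-unit store within one abundance
period (50.54 < 60 steps), and a 40-step famine is just long enough to kill
it (39.72 < 40).
"""

from thriftsim import EnergyBudget, max_energy, time_to_accumulate, time_to_starve

for e_s in (2.0, 3.0):
    budget = EnergyBudget(E_s=e_s, M_b=0.05, E_T=20.0)
    print(f"portion size E_s = {e_s}:")
    print(f"  stationary maximum E_max = E_s/M_b      = {max_energy(budget):.0f}")
    if e_s == 3.0:
        t_up = time_to_accumulate(budget, 55.0, from_zero=True)
        t_down = time_to_starve(budget, 55.0)
        print(f"  steps from zero energy to 55 (feeding) = {t_up:.2f}")
        print(f"  steps from 55 to zero (total famine)   = {t_down:.2f}")
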