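# Model and methods

## The model in brief

Agents forage on a `side × side` torus (default 41) whose cells hold at most
one food portion of energy `E_s`. Time is discrete. Each step runs in six
phases:

1. living agents are shuffled into a fresh uniform processing order;
2. in that order each agent eats (if its cell holds food and its energy is
   below its accumulation level), perceives its Moore neighborhood (DF and FF
   only) and resolves a planned move;
3. perception cost and basal expenditure are charged; agents at energy ≤ 0
   die;
4. survivors apply their decision heuristic to their accumulation level,
   synchronously;
5. cells that are still empty regenerate;
6. a per-step record is emitted.

### Metabolism

Basal expenditure is `M_b·E` above the threshold `E_T` and the constant
`M_b·E_T` below it; `E_T·M_b` is the minimum energy an agent must find per
step to stay alive, and prevents metabolic scaling from making starvation
asymptotic. Basal expenditure is assessed on the energy the agent carried at
the **start of its turn** and deducted at the end of the step. This convention
makes a feeding sedentary agent follow the recursion
`E(t) = E(t−1) + E_s − M_b·E(t−1)` exactly, hence the closed forms in
`analytics` (trajectory, accumulation time, starvation time) are exact
oracles for the engine, and the stationary maximum is exactly
`E_max = E_s/M_b`. (Charging basal on post-consumption energy instead would
shift the stationary end-of-step energy to `E_s(1−M_b)/M_b` and break the
closed-form correspondence.)

### Movement

A decided move succeeds with probability `exp(E−E_s)` below `E_s`,
`exp(E_T−E)` above `E_T`, and 1 in the band `[E_s, E_T]` — energy-depleted
agents are too weak and heavy agents too encumbered to move reliably. The
cost `C_m·E` is charged only on realized displacement: a failed roll moves no
mass and costs nothing. (The alternative — charging on the attempt — makes
every feast-famine population go extinct, because famished high-energy agents
attempt moves they can essentially never win.) The success probability is
evaluated on post-consumption energy. Perceiving strategies pay `C_p` every
step, food found or not.

### Storage ceiling

The accumulation level `L` is a hard ceiling on eating: an agent eats only
while `E < L`, a portion is consumed whole, and intake is truncated at `L`
(the excess is logged as waste in the energy audit). When a heuristic makes
an agent adopt a ceiling *below* its current energy, the energy is kept — the
agent simply cannot eat until basal expenditure brings it back under the new
ceiling. Clipping the energy instead would destroy stored energy on every
transient label change and, under imitation, collapses the population; with
the chosen semantics the ceiling constraint `E ≤ L` holds exactly wherever
levels are immutable (repetition runs) and transient overshoot decays at rate
`M_b` otherwise.

### Regeneration timing

Regeneration is *immediate*: a portion consumed during step `t` reappears
within the same step with probability `p_g(t)`, visible to agents later in
the processing order. Under full abundance (`p_g = 1`) food is therefore
continuously available and cell-sharing agents do not compete; under famine
(`p_g = 0`) consumption is final and a cell's single portion goes to the
earliest agent in the shuffled order. Cells still empty at the end of step
`t` draw once with `p_g(t+1)` — the probability of the time unit in which the
food becomes available. Two consequences matter at phase boundaries: the
grid is full when a famine begins (abundance replaces what its last step
consumed), and full again when abundance returns (a famine of `t_fam` steps
deprives agents of regeneration for exactly `t_fam` steps). This is the
unique timing convention consistent with the schedule calibration
`t_starve(55) = 39.72 < t_fam = 40 < 41.4 = t_starve(60)`: the survival
margin of a fully stocked agent is a fraction of one step, so an off-by-one
in famine length inverts the selection result the model exists to exhibit.

### Communities and heuristics

An agent's community is the set of living agents in its own cell, extended to
the eight adjacent cells when its strategy perceives (DF, FF); the agent is a
member of its own community, so the alone case is well defined under every
rule. Repetition keeps the level; imitation adopts the level of a uniformly
random member; inquiring adopts the level of the member with maximal energy,
ties broken uniformly. Updates are computed from end-of-step energies and
positions, after deaths, and commit simultaneously. Adopted levels are always
values present in the community, so the set of levels can only shrink.

### Initial conditions

All cells start food-bearing (both seasonal experiments open in abundance;
constant-`p_g` runs equilibrate within a few steps). Agents are spread over
cells drawn uniformly *without replacement* — approximately uniform density,
at most one agent per cell at the canonical population sizes — with any
excess over the cell count placed uniformly at random. Initial energy is 2
for every agent. Placement matters: with independent uniform placement about
63% of a density-1 population shares a cell at start, those sharers dominate
first-famine mortality, and the feast-famine population equilibria drop by a
third.

## Parameters

| symbol | meaning | default |
|---|---|---|
| `grid_side` | lattice side (torus) | 41 |
| `E_T` | metabolic/movement threshold (energy) | 20 |
| `M_b` | basal metabolic rate (per step) | 0.05 |
| `C_p` | perception cost (energy/step) | 0.01 |
| `C_m` | movement cost (fraction of energy) | 0.02 |
| `E_s` | food portion (energy) | 2.0 constant / 3.0 seasonal |
| `initial_energy` | starting energy | 2 |
| `t_ab`, `t_fam` | mean abundance/famine lengths (steps) | 60, 40 |
| `STD` | schedule standard deviation (steps) | 0, 1 or 5 |
| `n_cycles` | abundance–famine cycles | 10 |
| replicates | seeded runs per configuration | 30 |

Period lengths are drawn from the stated normals, rounded to the nearest
integer and clipped below at 1. Replicate `r` of an ensemble uses seed
`master + r`; distinct configurations in a sweep use `master + 100000·k`.
With a fixed seed every run is bit-reproducible.

## Summary statistics

Per-step records hold population and mean energy by (strategy, level,
heuristic) group, populations counted after the step's deaths. Per-cycle
summaries average over every step of a cycle (both phases). Two energy
statistics are exposed: `mean_energy` averages only steps on which the group
is alive, while `mean_energy_filled` counts steps with an extinct group as
zero — the convention of per-cycle energy curves, where a population sliding
into extinction shows a declining energy trace rather than a frozen plateau.
A per-step audit (portions eaten, truncation waste, movement, perception and
basal costs, energy removed by deaths) closes the energy books to
floating-point accuracy and is checked by a property test.

## Problem sizes used by the tests and the acceptance script

The feast-famine ensemble checks run the full canonical configuration
(41×41, 840+840 agents, 1000 steps) at 30 replicates per heuristic; the
constant-environment checks use 10 replicates of the strategy-S slice at five
regeneration probabilities. Unit and property tests use small lattices
(5–13 cells a side) and short schedules, which exercise every code path at a
fraction of the cost. The engine is array-oriented (struct-of-arrays over
agents), so one full 1000-step replicate takes well under a second.

## Known limitations

- The model of the source system is itself stylized: no reproduction, aging
  or predation (populations only shrink), fixed foraging strategy per agent,
  spatially homogeneous regeneration. Results speak to the modeled ecology,
  not directly to physiology.
- The feast-famine selection result sits deliberately on a knife edge
  (survival margins below one step); quantities downstream of that edge —
  the imitation-heuristic level composition at the final step, and the exact
  cycle at which the level-55 stragglers finish going extinct — are sensitive
  to micro-conventions of scheduling and contention that no description pins
  down completely, and ensemble means for those two quantities should be read
  with generous error bars.
- In constant environments with the below-threshold expenditure floor, a
  sedentary agent's survival requires `p_g·E_s ≥ E_T·M_b`; storage capacity
  therefore only differentiates outcomes near that break-even point, and
  no storage level can rescue populations at `p_g` well below it.
- Intermediate regeneration probabilities combined with immediate
  within-step regeneration let a cell feed more than one same-step occupant
  with geometrically decaying probability; at the canonical parameter values
  (seasonal `p_g ∈ {0,1}`, constant runs dominated by single occupancy) this
  has no measurable effect.
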