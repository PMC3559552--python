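"""Construct the initial homeostatic world and inspect its composition.

Builds the 80x50 plasma grid with 50 leukocytes (each a 40x30 grid with an
11x11 nucleus), fills every cell with the derived homeostatic copy numbers
and seeds the plasma cytokine pools, then prints the per-species totals.
"""

from endoabm import SimulationConfig, build_world, derive_initial_counts
from endoabm import species as sp

d = derive_initial_counts()
print("copy-number budget:", d.budget, "molecules per cell")
print("unit copy number f =", d.f, " life-scale =", d.life_scale, "ticks/hour")

world = build_world(SimulationConfig(seed=1))
counts = world.counts_by_species()
for name, n in zip(sp.SPECIES_NAMES, counts):
    if n:
        print(f"{name:>9s}: {n:6d}")
print("molecules per cell:", counts.sum() - 300, "/ 50 cells -> 290 each")
print("plasma P and A pools: 150 each (10% of the summed cellular pools)")

states = world.cell_states()
print("cell states at t=0: pro", (states == 1).sum(),
      "anti", (states == -1).sum(), "homeostatic", (states == 0).sum())
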