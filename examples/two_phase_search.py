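"""Two-phase conformer search on a surface with a hidden off-grid well.

The toy surface has the usual threefold wells near 60/180/300 degrees
plus one narrow extra well near 95 degrees.  The systematic phase,
seeded with the three intuitive angles, finds only the three intuitive
minima; the Monte Carlo phase samples random torsional points outside
the exclusion hypercubes of everything already stored and lands in the
hidden well.
"""

import numpy as np

from torsearch import PreconditionedAngles, SearchConfig, SearchEngine
from torsearch.fixtures import off_grid_pes
from torsearch.reports import efficiency_table

pes = off_grid_pes()  # extra well near 95 degrees, basin ~ +-15 degrees
engine = SearchEngine(pes.zm, pes, SearchConfig(
    seed=11, batches=[{"cycles": 150, "d": 10.0}]))

state = engine.run_systematic(PreconditionedAngles.sp3_chain(1))
print("after systematic phase:",
      sorted(round(float(c.phi_eq[0]), 1) for c in state.equilibria))

engine.run_stochastic(state)
print("after stochastic phase:",
      sorted(round(float(c.phi_eq[0]), 1) for c in state.equilibria))

print()
print(efficiency_table(state, t=1).to_string(index=False))
print()
print("K1/K2 count generated guesses per phase, K1*/K2* the ones that became")
print("trials, J1/J2 the conformers each phase contributed.  The ~91-degree")
print("minimum (the well centre shifts slightly off 95 under the threefold")
print("background) appears only after the stochastic phase.")
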