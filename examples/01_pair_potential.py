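"""Landmarks of the hydropathy-scaled (Ashbaugh-Hatch) pair potential.

The attraction between two beads is tuned by a single dimensionless
hydropathy lambda: lambda = 1 is a plain Lennard-Jones well of depth
epsilon, lambda = 0 switches the attraction off (WCA repulsion), and
lambda = -1 (the DNA-DNA setting) is repulsive everywhere.
"""

import numpy as np

from pdcondensate import ForceFieldParams, pair_energy, pair_sigma
from pdcondensate.forcefield import R_MIN_FACTOR

ff = ForceFieldParams()

print("combination rule sigma_ij (Å):")
for pair in (("protein", "protein"), ("protein", "dna"), ("dna", "dna")):
    print(f"  {pair[0]:>7s}-{pair[1]:<7s} {pair_sigma(*pair, ff):6.2f}")

sigma = ff.sigma_P
r_min = R_MIN_FACTOR * sigma
print(f"\nprotein-protein potential at the LJ minimum r = {r_min:.2f} Å:")
for lam in (-1.0, 0.0, 0.5, 1.0, 2.0, 3.5):
    u = pair_energy(r_min, sigma, lam, ff)
    print(f"  lambda = {lam:+.1f}  ->  U = {u:+.3f} kcal/mol")
print("The well depth scales linearly with lambda (-lambda * epsilon);")
print("lambda >= 1 deepens attraction, lambda < 0 leaves pure repulsion.")

r = np.linspace(45.0, 150.0, 6)
print("\nradial profile at lambda = 1 (kcal/mol):")
print("  r(Å): " + "  ".join(f"{x:7.1f}" for x in r))
print("  U   : " + "  ".join(f"{pair_energy(x, sigma, 1.0, ff):7.3f}"
                             for x in r))
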