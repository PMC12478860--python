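"""Equilibrium statistics of one model DNA chain.

Samples the 300 K ensemble of a 250-bead chain (one bead per base pair)
with the pivot Monte Carlo sampler and reports the mean radius of
gyration and the persistence length, compared against the independent
single-angle Boltzmann quadrature prediction.
"""

import numpy as np

from pdcondensate import sample_chain, persistence_length
from pdcondensate.chain_metrics import quadrature_persistence_length

L = 250
confs, rgs = sample_chain(L, n_moves=25_000, burn_in=5_000, sample_every=25,
                          seed=2, return_series=True)
res = persistence_length(confs)
oracle = quadrature_persistence_length(20.0, res["bond_length"])

print(f"chain length            : {L} beads (contour {(L-1)*5.5:.1f} Å)")
print(f"samples                 : {len(rgs)} decorrelated conformations")
print(f"mean radius of gyration : {np.mean(rgs):.1f} Å "
      f"(std {np.std(rgs):.1f} Å)")
print(f"persistence length      : {res['l_p']:.0f} Å from bond correlations")
print(f"quadrature prediction   : {oracle:.0f} Å (single-angle Boltzmann)")
print("\nAt K_theta = 20 kcal/mol/rad^2 the chain behaves like dsDNA:")
print("l_p of a few hundred Å and R_g near 295 Å for 250 bp.")
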