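"""Multi-mode diffusion decomposition from displacement distributions.

Proteins in a condensate sample several dynamical environments (dilute,
interfacial, dense, DNA-bound ...).  A mean-square displacement averages
them away; the radial displacement distribution P(r, t) instead resolves
them as a mixture of Gaussian propagators with fractions p_i and
diffusivities D_i.  Here a known 5-mode ensemble is decomposed blindly.
"""

import numpy as np

from pdcondensate import (distribution_from_samples, fit_diffusion_modes,
                          sample_displacements, select_mode_count)

p_true = [0.30, 0.25, 0.20, 0.15, 0.10]
d_true = [1e5, 1e4, 1e3, 1e2, 1e1]          # Å^2/ns, decade-spaced
lags = (0.5, 1.0, 2.0)

dists = [distribution_from_samples(
    sample_displacements(p_true, d_true, t, 150_000, seed=int(10 * t)),
    t, n_bins=500) for t in lags]

n_sel = select_mode_count(dists, n_max=6)
fit = fit_diffusion_modes(dists, n_sel)

print(f"selected mode count : {n_sel} (truth: 5)")
print("mode   p (truth)    D Å^2/ns (truth)")
for i, (pi, di) in enumerate(zip(fit.p, fit.D), 1):
    print(f"  D_{i}  {pi:.3f} ({p_true[i-1]:.2f})   "
          f"{di:10.1f} ({d_true[i-1]:.0f})")
per_lag = np.array(list(fit.per_lag_D.values()))
spread = np.abs(per_lag / per_lag.mean(axis=0) - 1.0).max()
print(f"max D_i variation across lags: {100 * spread:.1f}% "
      "(plateau = Brownian modes)")
print("\nThe two slowest modes are the signature of DNA-bound protein")
print("populations; without DNA in the condensate only three modes appear.")
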