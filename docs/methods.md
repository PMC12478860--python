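# Methods

This note records the models, estimators, numerical choices, and known
limitations behind `pdcondensate`, at the level of detail a user needs to
judge what a result does and does not mean.

## Interaction model

Two species: a one-bead protein (σ_P = 50 Å — about twice the radius of
gyration of compact DNA-binding proteins such as TFAM or HP1α — and a
deliberately reduced mass of 5000 g/mol for faster diffusive relaxation)
and a DNA monomer representing one base pair (σ_D = 5 Å, 500 g/mol).
DNA chains carry harmonic bonds `K_b (r − r0)²` (K_b = 20 kcal/mol/Å²,
r0 = 5.5 Å) and harmonic bending `K_θ (θ − θ0)²` about the straight angle.
Both harmonic terms are implemented *without* the conventional 1/2
prefactor: the spring constants are used exactly as defined, so anyone
comparing against a 1/2-convention code must double theirs.

Nonbonded interactions use the Ashbaugh–Hatch decomposition of the
Lennard-Jones potential: the repulsive core is kept at full strength while
the attractive tail is scaled by a hydropathy λ_ij.  The two branches meet
continuously at 2^(1/6) σ_ij with value −λε, and the derivative is
continuous there as well, so forces contain no impulsive terms.  λ_DD = −1
makes DNA–DNA contacts repulsive at all separations.  Directly bonded
(1–2) DNA pairs are excluded from nonbonded interactions; 1–3 pairs are
not (their repulsion at ~11 Å is ≈ 0.007 kcal/mol, dynamically
negligible, so this choice mostly affects bookkeeping).

**Cutoff.** The nonbonded potential is truncated, unshifted, at
r_cut = 3 σ_ij (configurable).  The residual discontinuity at the cutoff
is |λ| · 0.0011 kcal/mol ≈ 0.002 kT, far below thermal noise; an energy
shift was deliberately omitted to keep the well depth exactly −λε.

## Dynamics

Langevin dynamics with per-bead friction γ_i = m_i/t_damp: every bead
relaxes with the same damping time regardless of mass.  The integrator is
the BAOAB splitting of velocity Verlet — deterministic half-kick, half
drift, exact Ornstein–Uhlenbeck velocity update, half drift, half-kick —
which satisfies fluctuation–dissipation at finite time step and reduces
exactly to symplectic velocity Verlet when the thermostat is disabled
(t_damp = ∞).  The defaults are the production conditions (300 K,
t_damp = 1000 ps, dt = 10 fs); short validation runs use t_damp ≈ 1 ps so
velocities decorrelate within the run — at 1000 ps damping a system needs
≫ ns to thermalize and equipartition could not be tested in seconds.

Internal units are Å, g/mol, kcal/mol; the derived time unit is
√(g/mol · Å²/(kcal/mol)) ≈ 48.89 fs, and all user-facing times (fs, ps,
ns) are converted at the boundary.

Forces are evaluated either over all pairs (the correctness oracle) or
through a Verlet list built on a periodic k-d tree with a skin, rebuilt
once any bead has moved more than half the skin; the two paths agree to
relative 1e-10 (the residual is floating-point summation order).  A bead
displacing more than half a box edge in one step aborts the run with a
diagnostic — this catches both oversized time steps and overlapping
initial conditions.

**Initial conditions.** Mixtures start as a dense droplet: all molecules
placed uniformly in a central sphere (default radius box/4), with
rejection-based overlap relief (0.8 σ_PP among proteins, 0.8 σ_PD between
DNA beads and proteins, 0.8 σ_DD between chains).  DNA conformations are
grown as persistent random walks whose deflection angles are drawn from
the bending Boltzmann weight, so chains start near their equilibrium
stiffness.  Exact reproduction of any particular engine's initial
transient is not attempted; only equilibrium properties are contracted.

## Monte Carlo chain sampler

Isolated-chain equilibrium averages (R_g, persistence length) come from a
Metropolis sampler rather than Langevin dynamics: a pivot move resamples
one interior bend angle *directly from its Boltzmann distribution* (with a
uniform twist about the new bond direction) and rigidly rotates the
downstream arm, and a bond move resamples one bond length from its exact
harmonic marginal (r² exp(−βK_b(r−r0)²), by rejection under a Gaussian
envelope).  Because both proposals draw from the bonded Boltzmann weights,
the acceptance test reduces to the change in nonbonded (excluded-volume)
energy, keeping the sampler exact for the full potential while R_g
decorrelates within tens of accepted moves.  The chain is sampled in open
space; the boxes used for single-chain work exceed three contour lengths,
so periodic images never interact.

Consistency check built into the test suite: for the default stiffness the
sampled persistence length agrees within a few percent with the
independent single-angle quadrature l_p = −b/ln⟨cos φ⟩, and the sampled
250-bead R_g (~290–296 Å) matches the wormlike-chain closed form for that
l_p (~294 Å).

## Cluster and composition analysis

Clusters are connected components of the bead contact graph under
minimum-image distances (periodic k-d tree + sparse connected components;
validated against a brute-force union–find oracle).  The default contact
criterion is the single cutoff 1.5 σ_PD = 41.25 Å.  Note a geometric
subtlety: that cutoff is *smaller than one protein diameter*, so two
proteins in direct contact (pair minimum at ~56 Å) are never linked by it
— protein-only condensates are invisible to the single-cutoff criterion.
`cluster_beads(per_pair=True)` therefore offers a species-resolved
criterion 1.5 σ_ij, which the pipeline uses by default; the global-cutoff
mode remains for strictly DNA-bridged cluster definitions.

Largest-cluster composition: f_P counts protein beads inside the largest
cluster; f_D counts all beads of every DNA chain with at least one bead
inside (the any-bead rule — one touching bead recruits the whole chain).
A protein is "DNA-bound" when its minimum-image distance to any DNA bead
is at most σ_P + σ_D = 55 Å; the dense-phase variant restricts the
numerator and denominator to largest-cluster members.

A caveat on cutoff monotonicity: f_P and f_D grow monotonically with the
contact cutoff only while one cluster stays dominant.  When several
comparable clusters coexist, a merge elsewhere can overtake the previous
largest cluster and the fractions can drop discontinuously; the
composition observables are meaningful in condensed regimes, which is
where they are used.

**Block averaging.** Time series are split into five equal blocks
(truncating any remainder), the first block is discarded as equilibration,
and mean ± stderr are computed from the remaining block means.  Both
counts are configurable.

## Density profiles and coexistence

Radial profiles histogram protein number density in spherical shells
around the center of mass of largest-cluster proteins.  The COM is
computed by the circular-mean construction (each coordinate mapped to an
angle on the torus), which is well defined even when the cluster straddles
a periodic boundary.  Shell densities are counts/volume in beads/nm³ and
conserve the total count exactly.  (To convert: 1 bead/nm³ ≈ 1.66 mM.)

Multiphasic profiles are fitted with a two-step tanh superposition

    ρ(r) = ρ_dil + (ρ_II − ρ_dil)/2 [1 − tanh((r − R_II)/w_II)]
                 + (ρ_I − ρ_II)/2 [1 − tanh((r − R_I)/w_I)]

which reduces to a single interface when the inner amplitude vanishes.
Numerical choices that matter:

* the fit is parameterized with R_II = R_I + ΔR, ΔR ≥ 0, so the
  interphase ordering is structural rather than post-processed;
* ten deterministic multi-starts seeded from quantiles of the radial
  range; lowest residual wins, ties broken by smaller R_I;
* shells are weighted by √(shell volume): for count histograms the
  density variance scales inversely with shell volume, and unweighted
  fits let the handful of counts in the innermost shells fake an inner
  step;
* interface widths are bounded below by half a bin (narrower interfaces
  are unresolvable at the chosen binning);
* a fitted single step that landed in the inner-tanh slot with a
  vanishing outer amplitude is promoted to the outer slot (the two-step
  model can represent one step either way);
* the `multiphasic` flag requires the inner amplitude to exceed both a
  significance multiple (default 3) of the rms residual and 2% of the
  profile maximum — the second condition prevents a noise-free
  single-step profile (rms ≈ 0) from being declared multiphasic by an
  epsilon-sized inner step.

Coexistence concentrations: per frame, the dense-phase density is the mean
profile density over the innermost plateau (r < R_inner − 2w) and the
dilute-phase density the mean beyond the outermost interface
(r > R_outer + 2w); frames without a condensate (largest cluster under 10%
of proteins) contribute the global density to the dilute branch only.
Both branches are block-averaged, and the fraction of frames with a
persistent inner step is reported so non-converging (multiphasic)
envelopes can be recognized.

## Diffusion-mode decomposition

The radial displacement distribution P(r, t) is accumulated over all
proteins and all frame pairs separated by the lag (overlapping origins;
the correlation between origins widens error bars but leaves expectations
unbiased).  Displacements use unwrapped coordinates.

The n-mode model is the population-weighted sum of 3-D Gaussian
propagators with fractions p_i (simplex) and diffusivities D_i.  The fit
minimizes weighted least squares of the **per-bin probability mass**,
computed through the closed-form radial CDF
erf(x) − (2/√π) x e^(−x²), x = r/√(4Dt) — fitting the density at bin
centers instead carries a discretization bias whenever a slow mode is
narrower than a bin, and was observed to move fitted D by ~10% between
300- and 2000-bin histograms; the CDF formulation brings that spread under
~1%.  Weights are 1/max(P, 0.01 · P_max).  Optimization runs over
(log10 D_i, softmax logits of p), with ten deterministic starts whose
log-spaced D ladders span the r²/4t range of the data; fitted modes are
reported sorted by descending D.

**Mode-count selection.** Fits are computed for n = 1 … n_max; the
selected count is the largest n whose refinement step reduced the rms
residual by at least 20% (relative), with scanning stopped at the first
fit containing a component below p_min = 0.01 (a superfluous mode).
Judging each refinement step on its own matters: on 5-mode data the gain
sequence can dip below threshold at n = 3 before rising sharply at
n = 4–5, and a stop-at-first-failure rule would underselect.  Both
thresholds are configurable.  Per-lag fits are kept so the constancy of
D_i across lags (the Brownian plateau) can be verified.

The package also ships the inverse direction — a known-truth sampler that
draws radial displacements from a given (p, D) mixture — used for
round-trip validation: for decade-spaced modes and n ∈ {1, 2, 3, 5},
recovery is within 5% on D and 0.02 on p, and the selected mode count is
stable across 300/500/1000/2000 bins.

## What the synthetic generators do and do not emulate

The fixture generators (displacement mixtures, double-tanh profiles with
multiplicative noise, dominant-cluster configurations) provide exact
ground truth for estimator validation.  They emulate the *statistical
structure* of condensate data — multimodal propagators, stepped radial
profiles, Poisson-like shell noise — but not its physical couplings:
no exchange of proteins between modes within a lag, no correlation
between density and mobility, no slow collective interface fluctuations.
Passing round-trip tests therefore certifies the estimators, not the
thermodynamics of any particular simulated state point; statements about
phase behavior always require the simulation engine itself.

## Problem sizes

Validation and demonstration runs use desk-scale systems chosen as the
smallest sizes at which each observable is statistically meaningful:
single chains of 60–250 beads, mixtures of ~50–200 beads, free gases of
~1000 particles, displacement ensembles of 1.5–2 × 10⁵ samples, and
synthetic profiles of 50–100 shells.  The engine itself has no hard-coded
size assumptions; the published-scale mixture (10,000 beads, 2000 Å box)
builds and integrates with the same code paths, and the configuration
defaults are exactly those production conditions.

## Known limitations

* No electrostatics, explicit solvent, sequence specificity, or DNA
  helical structure — deliberate minimalism inherited from the model.
* The all-pairs/numpy force engine favors clarity over throughput;
  microsecond production runs at 10⁴ beads call for a dedicated MD engine
  while this package covers model definition, desk-scale simulation, and
  the full analysis stack.
* NVT (Langevin) only; no constant-pressure ensemble.
* The single-cutoff cluster criterion cannot register direct
  protein–protein contacts (see above); the per-pair mode is the
  physically meaningful default for protein-rich condensates.
* Persistence length is estimated from bond-vector correlations with an
  exponential fit window; for chains whose correlation decays within one
  bond (K_θ → 0) the result is flagged `sub_bond` rather than forced.
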