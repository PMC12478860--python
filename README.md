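# pdcondensate

Coarse-grained simulation and analysis of **protein–DNA biomolecular
condensates** — membraneless assemblies formed by liquid–liquid phase
separation of DNA-binding proteins and nucleic acids.

The package is aimed at researchers who want to dissect how *homotypic*
(protein–protein, λ_PP) and *heterotypic* (protein–DNA, λ_PD)
interactions, DNA chain length, and DNA flexibility shape condensate
formation, internal architecture, and protein dynamics — at desk scale,
from Python.

## The model

Proteins are single spherical beads (σ_P = 50 Å, m = 5000 g/mol); DNA is a
bead–spring polymer with one bead per base pair (σ_D = 5 Å, m = 500 g/mol):

* bonds: `U_bond = K_b (r − r0)²` with K_b = 20 kcal/mol/Å², r0 = 5.5 Å
* bending: `U_angle = K_θ (θ − θ0)²` with θ0 = 180°; K_θ = 20 kcal/mol/rad²
  reproduces dsDNA stiffness (persistence length of a few hundred Å)
* nonbonded (Ashbaugh–Hatch): the attractive tail of a Lennard-Jones
  potential (ε = 0.2 kcal/mol, arithmetic-mean σ_ij) scaled by a hydropathy
  λ_ij:

  ```
  U_nb(r) = U_LJ(r) + (1 − λ)ε    for r ≤ 2^(1/6) σ
          = λ U_LJ(r)             otherwise
  ```

  λ_DD = −1 keeps DNA–DNA purely repulsive; λ_PP and λ_PD are the two
  control parameters of the phase diagram.

Dynamics are Langevin (BAOAB velocity-Verlet) at 300 K with per-bead
friction γ_i = m_i / t_damp (t_damp = 1000 ps, dt = 10 fs) in a periodic
cube (2000 Å for the full-scale mixtures, 1:1 protein:DNA-bead
stoichiometry).  A pivot Monte Carlo sampler provides fast equilibrium
ensembles for isolated chains.

The analysis stack covers:

* distance-based clustering with largest-cluster composition
  `f_P = N_P^cluster/N_P^total`, `f_D = N_D^cluster/N_D^total`
  (a DNA chain counts wholly once any bead touches the cluster)
* DNA radius of gyration, compaction ratios, persistence length
* radial density profiles about the largest-cluster protein COM with a
  **double hyperbolic tangent** fit that locates the interphases of
  multiphasic ("phase-in-phase") condensates and yields coexistence
  concentrations
* a **multi-mode diffusion decomposition**: the radial displacement
  distribution is fitted as
  `P(r,t) = Σ_i p_i · 4πr²/(4πD_i t)^{3/2} · exp(−r²/4D_i t)`,
  with automatic selection of the number of diffusive modes
* block averaging (five equal blocks, first discarded) for error bars

## Worked example

Equilibrium statistics of one 250-bp model DNA chain
(`examples/02_single_chain_stiffness.py`):

```
chain length            : 250 beads (contour 1369.5 Å)
samples                 : 800 decorrelated conformations
mean radius of gyration : 289.6 Å (std 39.8 Å)
persistence length      : 362 Å from bond correlations
quadrature prediction   : 370 Å (single-angle Boltzmann)
```

The mean R_g ≈ 290 Å and l_p ≈ 360–390 Å identify the default stiffness as
dsDNA-like; the quadrature line is an independent closed-form check of the
sampled bond-correlation decay.

Blind decomposition of a five-mode displacement ensemble
(`examples/05_diffusion_modes.py`):

```
selected mode count : 5 (truth: 5)
mode   p (truth)    D Å^2/ns (truth)
  D_1  0.298 (0.30)      99928.1 (100000)
  D_2  0.250 (0.25)      10013.7 (10000)
  D_3  0.200 (0.20)       1005.7 (1000)
  D_4  0.151 (0.15)         99.4 (100)
  D_5  0.101 (0.10)         10.0 (10)
max D_i variation across lags: 1.6% (plateau = Brownian modes)
```

Each `examples/0*.py` script is a short, self-contained demonstration of
one capability (pair potential, chain stiffness, cluster composition,
multiphasic profile fitting, diffusion modes, full pipeline).

A thin CLI wraps the library for shell use:

```bash
pdcondensate pipeline --config run.yaml --out rundir
```

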