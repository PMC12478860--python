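"""Equilibrium Monte Carlo sampling of a single DNA chain.

Pivot-style Monte Carlo is the efficient route to the equilibrium ensemble
of one bead-spring chain: a pivot move resamples a single interior bend
angle directly from its Boltzmann distribution and rigidly rotates the
downstream arm, so the radius of gyration decorrelates within tens of
accepted moves instead of the microseconds a damped Langevin run needs.
Bond lengths are resampled from their exact harmonic marginal by rigid
translation of the downstream arm.  Because both proposals draw from the
bonded Boltzmann weights, the Metropolis-Hastings acceptance reduces to the
change in *nonbonded* (excluded-volume) energy alone, which keeps the
sampler exact for the full potential.

The chain lives in open space (the simulation boxes used for single-chain
runs exceed three contour lengths, so periodic images never interact).
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceFieldParams, R_MIN_FACTOR
from .units import KB

__all__ = ["sample_chain", "chain_nonbonded_cross_energy"]


def _bend_phi_sampler(kappa: float, rng: np.random.Generator):
    """Draw deflection angle phi from P(phi) ∝ exp(-kappa phi^2) sin(phi)."""
    if kappa < 1e-9:
        return np.arccos(rng.uniform(-1.0, 1.0))
    sd = np.sqrt(0.5 / kappa)
    while True:
        phi = abs(rng.normal(0.0, sd))
        # envelope exp(-kappa phi^2); accept with the remaining sin(phi)
        if phi < np.pi and rng.random() < np.sin(phi):
            return phi


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_rotation(perp, np.pi)
    axis = v / s
    return _axis_rotation(axis, np.arctan2(s, c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    kx, ky, kz = axis
    k = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def chain_nonbonded_cross_energy(head: np.ndarray, tail: np.ndarray,
                                 ff: ForceFieldParams,
                                 skip_adjacent: bool = True) -> float:
    """Nonbonded DNA-DNA energy between two chain segments.

    ``head`` ends at the pivot bead and ``tail`` starts just after it; the
    directly bonded pair (last head bead, first tail bead) is excluded.
    """
    sigma = ff.sigma_D
    lam = ff.lambda_DD
    cut = ff.cutoff_factor * sigma
    d = head[:, None, :] - tail[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", d, d)
    if skip_adjacent:
        r2[-1, 0] = np.inf
    mask = r2 < cut * cut
    if not np.any(mask):
        return 0.0
    r = np.sqrt(r2[mask])
    sr6 = (sigma / r) ** 6
    ulj = 4.0 * ff.epsilon * (sr6 * sr6 - sr6)
    inner = r <= R_MIN_FACTOR * sigma
    return float(np.sum(np.where(inner, ulj + (1.0 - lam) * ff.epsilon,
                                 lam * ulj)))


def sample_chain(L: int, ff: ForceFieldParams | None = None,
                 temperature: float = 300.0, n_moves: int = 30000,
                 burn_in: int = 5000, sample_every: int = 25,
                 seed: int = 0, bond_move_fraction: float = 0.2,
                 return_series: bool = False):
    """Sample equilibrium conformations of one L-bead chain.

    Returns an array of shape (n_samples, L, 3) of conformations recorded
    every ``sample_every`` moves after ``burn_in``; with
    ``return_series=True`` also returns the per-sample radius of gyration.
    Deterministic for a fixed seed.
    """
    if L < 3:
        raise ValueError("pivot sampling needs at least 3 beads")
    if ff is None:
        ff = ForceFieldParams()
    kt = KB * temperature
    kappa = ff.K_theta / kt
    rng = np.random.default_rng(seed)

    # start straight along x
    x = np.zeros((L, 3))
    x[:, 0] = np.arange(L) * ff.r0

    samples, rgs = [], []
    n_accept = 0
    for move in range(n_moves):
        if rng.random() < bond_move_fraction:
            # resample one bond length from r^2 exp(-beta K (r-r0)^2)
            j = int(rng.integers(1, L))
            u = x[j] - x[j - 1]
            b_old = np.linalg.norm(u)
            u /= b_old
            sd = np.sqrt(kt / (2.0 * ff.K_b))
            while True:
                b_new = rng.normal(ff.r0, sd)
                if b_new > 0 and rng.random() < (b_new / (ff.r0 + 4 * sd)) ** 2:
                    break
            shift = (b_new - b_old) * u
            tail_new = x[j:] + shift
            de = (chain_nonbonded_cross_energy(x[:j], tail_new, ff)
                  - chain_nonbonded_cross_energy(x[:j], x[j:], ff))
            if de <= 0 or rng.random() < np.exp(-de / kt):
                x[j:] = tail_new
                n_accept += 1
        else:
            # pivot: resample the bend angle at an interior bead and
            # rigidly rotate the downstream arm
            p = int(rng.integers(1, L - 1))
            u_prev = x[p] - x[p - 1]
            u_prev /= np.linalg.norm(u_prev)
            u_old = x[p + 1] - x[p]
            u_old /= np.linalg.norm(u_old)
            phi = _bend_phi_sampler(kappa, rng)
            psi = rng.uniform(0.0, 2.0 * np.pi)
            perp = np.cross(u_prev, rng.standard_normal(3))
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(u_prev, perp)
            u_new = (np.cos(phi) * u_prev
                     + np.sin(phi) * (np.cos(psi) * perp + np.sin(psi) * perp2))
            u_new /= np.linalg.norm(u_new)
            rot = _axis_rotation(u_new, rng.uniform(0.0, 2.0 * np.pi)) \
                @ _rotation_between(u_old, u_new)
            tail_new = (x[p + 1:] - x[p]) @ rot.T + x[p]
            de = (chain_nonbonded_cross_energy(x[:p + 1], tail_new, ff)
                  - chain_nonbonded_cross_energy(x[:p + 1], x[p + 1:], ff))
            if de <= 0 or rng.random() < np.exp(-de / kt):
                x[p + 1:] = tail_new
                n_accept += 1
        if move >= burn_in and (move - burn_in) % sample_every == 0:
            samples.append(x.copy())
            if return_series:
                centered = x - x.mean(axis=0)
                rgs.append(np.sqrt(np.mean(np.einsum("ij,ij->i", centered,
                                                     centered))))
    samples = np.array(samples)
    if return_series:
        return samples, np.array(rgs)
    return samples
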