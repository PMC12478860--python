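"""Force-field parameters and energy/force kernels.

The model has two species: a single-bead protein (P) and a bead-spring DNA
monomer (D, one bead per base pair).  Nonbonded interactions use the
Ashbaugh-Hatch form, a Lennard-Jones potential whose attractive tail is
scaled by a hydropathy parameter lambda_ij while the short-range repulsion
is left untouched:

    U_nb(r) = U_LJ(r) + (1 - lambda) * eps   for r <= 2^(1/6) sigma
            = lambda * U_LJ(r)               otherwise

with U_LJ(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6].  lambda = 1 recovers
plain LJ, lambda = 0 is purely repulsive (WCA) and lambda = -1 (the DNA-DNA
default) adds a soft repulsive tail.  Bonded DNA terms are harmonic in bond
length and in the interior angle, written without a 1/2 prefactor:

    U_bond  = K_b (r - r0)^2
    U_angle = K_theta (theta - theta0)^2,  theta0 = pi (straight chain)

All energies are kcal/mol, lengths Å, masses g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import yaml

__all__ = [
    "PROTEIN",
    "DNA",
    "ForceFieldParams",
    "pair_sigma",
    "lj_energy",
    "pair_energy",
    "pair_force",
    "bond_energy",
    "bond_force_mag",
    "angle_energy",
]

PROTEIN = "protein"
DNA = "dna"

_SPECIES = (PROTEIN, DNA)

#: position of the LJ minimum in units of sigma
R_MIN_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """All interaction constants of the coarse-grained model.

    Defaults are the published parameterization: eps = 0.2 kcal/mol,
    sigma_P = 50 Å (about twice the R_g of DNA-binding proteins such as
    TFAM or HP1alpha), sigma_D = 5 Å (one base pair), masses 5000 and
    500 g/mol, K_b = 20 kcal/mol/Å^2, r0 = 5.5 Å, K_theta = 20
    kcal/mol/rad^2 (dsDNA-like stiffness), theta0 = pi.  DNA-DNA
    attraction is switched off via lambda_DD = -1.
    """

    epsilon: float = 0.2
    sigma_P: float = 50.0
    sigma_D: float = 5.0
    mass_P: float = 5000.0
    mass_D: float = 500.0
    lambda_PP: float = 1.0
    lambda_PD: float = 1.0
    lambda_DD: float = -1.0
    K_b: float = 20.0
    r0: float = 5.5
    K_theta: float = 20.0
    theta0: float = np.pi
    cutoff_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.sigma_P <= 0 or self.sigma_D <= 0:
            raise ValueError("bead diameters must be positive")
        if self.K_b <= 0:
            raise ValueError("K_b must be positive")
        if self.K_theta < 0:
            raise ValueError("K_theta must be non-negative")
        if self.cutoff_factor <= R_MIN_FACTOR:
            raise ValueError(
                f"cutoff_factor must exceed 2^(1/6) ≈ {R_MIN_FACTOR:.4f}"
            )

    # -- species-indexed lookups -------------------------------------------

    def sigma_of(self, species: str) -> float:
        if species == PROTEIN:
            return self.sigma_P
        if species == DNA:
            return self.sigma_D
        raise ValueError(f"unknown species {species!r}; expected one of {_SPECIES}")

    def mass_of(self, species: str) -> float:
        if species == PROTEIN:
            return self.mass_P
        if species == DNA:
            return self.mass_D
        raise ValueError(f"unknown species {species!r}; expected one of {_SPECIES}")

    def lambda_of(self, species_i: str, species_j: str) -> float:
        key = frozenset((species_i, species_j))
        if key == frozenset((PROTEIN,)):
            return self.lambda_PP
        if key == frozenset((DNA,)):
            return self.lambda_DD
        if key == frozenset((PROTEIN, DNA)):
            return self.lambda_PD
        raise ValueError(
            f"unknown species pair ({species_i!r}, {species_j!r}); "
            f"expected labels from {_SPECIES}"
        )

    @property
    def sigma_PD(self) -> float:
        return 0.5 * (self.sigma_P + self.sigma_D)

    def max_cutoff(self) -> float:
        """Largest nonbonded cutoff radius over all species pairs, Å."""
        return self.cutoff_factor * max(self.sigma_P, self.sigma_D, self.sigma_PD)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown force-field keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ForceFieldParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_overrides(self, **kwargs) -> "ForceFieldParams":
        return replace(self, **kwargs)


def pair_sigma(species_i: str, species_j: str, ff: ForceFieldParams) -> float:
    """Arithmetic-mean combination rule sigma_ij = (sigma_i + sigma_j)/2, Å."""
    return 0.5 * (ff.sigma_of(species_i) + ff.sigma_of(species_j))


def lj_energy(r, sigma_ij: float, epsilon: float):
    """Standard Lennard-Jones energy 4 eps [(s/r)^12 - (s/r)^6]."""
    sr6 = (sigma_ij / np.asarray(r, dtype=float)) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def pair_energy(r, sigma_ij: float, lambda_ij: float, ff: ForceFieldParams):
    """Ashbaugh-Hatch nonbonded energy, truncated (unshifted) at the cutoff.

    Scalar or array ``r`` (Å); returns kcal/mol.  The two branches meet
    continuously at r = 2^(1/6) sigma where both equal -lambda * eps.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    eps = ff.epsilon
    ulj = lj_energy(r, sigma_ij, eps)
    inner = r <= R_MIN_FACTOR * sigma_ij
    u = np.where(inner, ulj + (1.0 - lambda_ij) * eps, lambda_ij * ulj)
    u = np.where(r >= ff.cutoff_factor * sigma_ij, 0.0, u)
    return u if u.ndim else float(u)


def pair_force(r, sigma_ij: float, lambda_ij: float, ff: ForceFieldParams):
    """Radial force -dU_nb/dr (kcal/mol/Å); positive values are repulsive.

    Both branches of the potential have the same derivative shape up to the
    lambda factor, and the derivative vanishes at the LJ minimum, so the
    force is continuous there for every lambda.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    eps = ff.epsilon
    sr6 = (sigma_ij / r) ** 6
    # -dU_LJ/dr = 24 eps (2 (s/r)^12 - (s/r)^6) / r
    flj = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    inner = r <= R_MIN_FACTOR * sigma_ij
    f = np.where(inner, flj, lambda_ij * flj)
    f = np.where(r >= ff.cutoff_factor * sigma_ij, 0.0, f)
    return f if f.ndim else float(f)


def bond_energy(r, ff: ForceFieldParams):
    """Harmonic bond energy K_b (r - r0)^2, kcal/mol (no 1/2 prefactor)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    u = ff.K_b * (r - ff.r0) ** 2
    return u if u.ndim else float(u)


def bond_force_mag(r, ff: ForceFieldParams):
    """Radial bond force -dU_bond/dr = -2 K_b (r - r0)."""
    r = np.asarray(r, dtype=float)
    f = -2.0 * ff.K_b * (r - ff.r0)
    return f if f.ndim else float(f)


def angle_energy(theta, ff: ForceFieldParams):
    """Harmonic bending energy K_theta (theta - theta0)^2, kcal/mol.

    ``theta`` is the interior bead-bead-bead angle in radians; theta0 = pi
    corresponds to a straight chain.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi + 1e-12)):
        raise ValueError("interior angle must lie in [0, pi]")
    u = ff.K_theta * (theta - ff.theta0) ** 2
    return u if u.ndim else float(u)
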