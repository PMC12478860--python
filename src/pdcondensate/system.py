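"""System construction: particle containers, topology, and mixture builders.

Positions are stored *wrapped* into [0, box_edge) with per-bead integer
image counts, so that unwrapped coordinates (needed for chain metrics and
displacement statistics) are always recoverable as
``wrapped + images * box_edge``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import PROTEIN, DNA, ForceFieldParams
from .units import KB

__all__ = [
    "ParticleSystem",
    "Topology",
    "chain_count",
    "build_mixture",
    "make_single_chain",
    "wrap_positions",
    "write_xyz_frame",
]


def wrap_positions(positions: np.ndarray, box_edge: float):
    """Wrap coordinates into [0, box) and return (wrapped, image_counts)."""
    images = np.floor(positions / box_edge).astype(np.int64)
    return positions - images * box_edge, images


@dataclass
class ParticleSystem:
    """Beads in a periodic cubic box.

    Attributes
    ----------
    positions : (N, 3) float array, wrapped into [0, box_edge)
    velocities : (N, 3) float array, internal units (Å per tau)
    species : (N,) array of labels, 'protein' or 'dna'
    masses : (N,) float array, g/mol
    box_edge : float, Å
    images : (N, 3) int array of periodic image counts
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    masses: np.ndarray
    box_edge: float
    images: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.asarray(self.species)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.images is None:
            self.positions, self.images = wrap_positions(self.positions, self.box_edge)
        else:
            self.images = np.asarray(self.images, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box_edge

    def is_protein(self) -> np.ndarray:
        return self.species == PROTEIN


@dataclass
class Topology:
    """Chain membership and bonded terms.

    Each DNA chain of N beads contributes N-1 bonds and N-2 angles;
    single-bead proteins contribute neither.  ``molecules`` lists
    (molecule_id, species, bead index array) with every bead in exactly
    one molecule.
    """

    molecules: list
    bonds: np.ndarray
    angles: np.ndarray
    chain_length: int

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def dna_chains(self) -> list:
        return [m for m in self.molecules if m[1] == DNA]

    def molecule_ids(self, n_beads: int) -> np.ndarray:
        """Per-bead molecule id array."""
        out = np.full(n_beads, -1, dtype=np.int64)
        for mol_id, _, idx in self.molecules:
            out[idx] = mol_id
        return out


def chain_count(dna_bead_budget: int, L: int) -> int:
    """Number of DNA chains of length ``L`` that exhaust a bead budget.

    The mixtures keep the total DNA bead number fixed (5000 in the
    published systems) while varying chain length, so ``L`` must divide
    the budget exactly.
    """
    if dna_bead_budget <= 0 or L <= 0:
        raise ValueError("bead budget and chain length must be positive")
    if dna_bead_budget % L != 0:
        raise ValueError(
            f"chain length {L} does not divide the DNA bead budget "
            f"{dna_bead_budget}; choose an exact divisor"
        )
    return dna_bead_budget // L


def _chain_topology(offsets: list, L: int) -> tuple:
    bonds, angles = [], []
    for start in offsets:
        idx = np.arange(start, start + L)
        bonds.append(np.column_stack([idx[:-1], idx[1:]]))
        if L >= 3:
            angles.append(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]))
    bonds = np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=np.int64)
    angles = np.concatenate(angles) if angles else np.empty((0, 3), dtype=np.int64)
    return bonds, angles


def _grow_chain(start: np.ndarray, L: int, ff: ForceFieldParams,
                rng: np.random.Generator, temperature: float = 300.0) -> np.ndarray:
    """Grow a persistent random walk with bond length r0.

    Deflection angles between successive bonds are drawn from the
    Boltzmann distribution of the bending potential, so the generated
    conformation is already close to the equilibrium stiffness.
    """
    kt = KB * temperature
    pos = np.empty((L, 3))
    pos[0] = start
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    pos[1] = pos[0] + ff.r0 * u if L > 1 else pos[0]
    for i in range(2, L):
        # rejection-sample deflection phi with weight exp(-K phi^2/kT) sin(phi)
        while True:
            phi = abs(rng.normal(0.0, np.sqrt(kt / (2.0 * max(ff.K_theta, 1e-3)))))
            if phi < np.pi and rng.random() < np.sin(phi):
                break
        psi = rng.uniform(0.0, 2.0 * np.pi)
        # rotate u by phi about a random perpendicular axis
        perp = np.cross(u, rng.standard_normal(3))
        perp /= np.linalg.norm(perp)
        perp2 = np.cross(u, perp)
        new_u = (np.cos(phi) * u
                 + np.sin(phi) * (np.cos(psi) * perp + np.sin(psi) * perp2))
        u = new_u / np.linalg.norm(new_u)
        pos[i] = pos[i - 1] + ff.r0 * u
    return pos


def build_mixture(n_protein: int, dna_length: int, dna_bead_budget: int,
                  box_edge: float, placement_radius: float | None = None,
                  seed: int = 0, ff: ForceFieldParams | None = None,
                  max_tries: int = 2000) -> tuple:
    """Build a protein + DNA mixture in a periodic cube.

    All molecules are placed inside a central sphere (default radius
    box_edge/4), mimicking a dense initial droplet; protein-protein
    overlaps below 0.8 sigma_PP are relieved by rejection sampling.
    DNA chains are grown as persistent random walks folded back into the
    placement region.  Deterministic for a fixed seed.
    """
    if ff is None:
        ff = ForceFieldParams()
    if n_protein <= 0 or dna_length <= 0 or dna_bead_budget <= 0:
        raise ValueError("counts must be positive")
    n_chains = chain_count(dna_bead_budget, dna_length)
    if placement_radius is None:
        placement_radius = box_edge / 4.0
    if placement_radius * 2.0 > box_edge:
        raise ValueError("placement region does not fit in the box")

    rng = np.random.default_rng(seed)
    center = np.full(3, box_edge / 2.0)

    def sample_in_sphere(radius: float) -> np.ndarray:
        while True:
            p = rng.uniform(-radius, radius, size=3)
            if np.dot(p, p) <= radius * radius:
                return center + p

    # proteins with overlap relief
    min_pp = 0.8 * ff.sigma_P
    prot = np.empty((n_protein, 3))
    for i in range(n_protein):
        for attempt in range(max_tries):
            cand = sample_in_sphere(placement_radius)
            if i == 0:
                break
            d = prot[:i] - cand
            d -= box_edge * np.round(d / box_edge)
            if np.min(np.einsum("ij,ij->i", d, d)) >= min_pp * min_pp:
                break
        else:
            raise RuntimeError(
                "could not place proteins without overlap; enlarge the "
                "placement region or reduce the protein count"
            )
        prot[i] = cand

    # DNA chains: grown freely, then rigidly shifted so the chain COM sits
    # inside the placement sphere; placements overlapping protein cores
    # (< 0.8 sigma_PD) or other chains (< 0.8 sigma_DD) are rejected so the
    # first integration step cannot blow up
    min_pd = 0.8 * ff.sigma_PD
    min_dd = 0.8 * ff.sigma_D
    prot_tree = cKDTree(prot) if n_protein else None
    chains: list = []
    placed_dna: np.ndarray | None = None
    for _ in range(n_chains):
        chain0 = _grow_chain(np.zeros(3), dna_length, ff, rng)
        chain0 -= chain0.mean(axis=0)
        for attempt in range(max_tries):
            if attempt and attempt % 50 == 0:
                chain0 = _grow_chain(np.zeros(3), dna_length, ff, rng)
                chain0 -= chain0.mean(axis=0)
            cand = chain0 + sample_in_sphere(placement_radius)
            if prot_tree is not None:
                d, _ = prot_tree.query(cand, k=1)
                if np.min(d) < min_pd:
                    continue
            if placed_dna is not None:
                d, _ = cKDTree(placed_dna).query(cand, k=1)
                if np.min(d) < min_dd:
                    continue
            break
        else:
            raise RuntimeError(
                "could not place DNA chains without overlap; enlarge the "
                "placement region"
            )
        chains.append(cand)
        placed_dna = cand if placed_dna is None \
            else np.concatenate([placed_dna, cand])

    positions = np.concatenate([prot] + chains) if chains else prot
    species = np.array([PROTEIN] * n_protein + [DNA] * (n_chains * dna_length))
    masses = np.where(species == PROTEIN, ff.mass_P, ff.mass_D)

    molecules = [(i, PROTEIN, np.array([i])) for i in range(n_protein)]
    offsets = [n_protein + k * dna_length for k in range(n_chains)]
    for k, off in enumerate(offsets):
        molecules.append((n_protein + k, DNA, np.arange(off, off + dna_length)))
    bonds, angles = _chain_topology(offsets, dna_length)

    system = ParticleSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        species=species,
        masses=masses,
        box_edge=box_edge,
    )
    topo = Topology(molecules=molecules, bonds=bonds, angles=angles,
                    chain_length=dna_length)
    return system, topo


def make_single_chain(L: int, conformation: str = "straight", seed: int = 0,
                      ff: ForceFieldParams | None = None,
                      box_factor: float = 3.0) -> tuple:
    """One isolated DNA chain in a box >= box_factor x contour length.

    ``conformation`` is 'straight' (bonds exactly at r0 along x) or
    'random' (persistent random walk).  The oversized box keeps the chain
    from interacting with its periodic images.
    """
    if L < 2:
        raise ValueError("a chain needs at least 2 beads")
    if conformation not in ("straight", "random"):
        raise ValueError(f"unknown conformation {conformation!r}")
    if ff is None:
        ff = ForceFieldParams()
    contour = (L - 1) * ff.r0
    box_edge = max(box_factor * contour, 10.0 * ff.r0)
    rng = np.random.default_rng(seed)
    if conformation == "straight":
        pos = np.zeros((L, 3))
        pos[:, 0] = np.arange(L) * ff.r0
    else:
        pos = _grow_chain(np.zeros(3), L, ff, rng)
    pos = pos - pos.mean(axis=0) + box_edge / 2.0

    species = np.array([DNA] * L)
    system = ParticleSystem(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=species,
        masses=np.full(L, ff.mass_D),
        box_edge=box_edge,
    )
    bonds, angles = _chain_topology([0], L)
    topo = Topology(molecules=[(0, DNA, np.arange(L))], bonds=bonds,
                    angles=angles, chain_length=L)
    return system, topo


_ELEMENT = {PROTEIN: "P", DNA: "D"}


def write_xyz_frame(fh, system: ParticleSystem, comment: str = "") -> None:
    """Append one extended-XYZ frame (species, x y z, image counts)."""
    fh.write(f"{system.n_beads}\n")
    fh.write(f'Lattice="{system.box_edge} 0 0 0 {system.box_edge} 0 0 0 '
             f'{system.box_edge}" Properties=species:S:1:pos:R:3:image:I:3 '
             f"{comment}\n")
    for sp, p, im in zip(system.species, system.positions, system.images):
        fh.write(f"{_ELEMENT[str(sp)]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                 f"{im[0]} {im[1]} {im[2]}\n")
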