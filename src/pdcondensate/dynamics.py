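"""Langevin dynamics: forces, BAOAB velocity-Verlet integration, trajectories.

The equations of motion are integrated with a velocity-Verlet splitting in
which the deterministic kicks/drifts sandwich an exact Ornstein-Uhlenbeck
velocity update (BAOAB).  The friction coefficient is gamma_i = m_i/t_damp,
i.e. every bead relaxes on the same damping time t_damp, and the noise
amplitude satisfies the fluctuation-dissipation theorem at finite time step.
With the thermostat disabled (t_damp = inf) the scheme reduces to plain
velocity Verlet.

Internal units are Å / (g/mol) / (kcal/mol); dt and t_damp are accepted in
fs and ps and converted on input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import DNA, PROTEIN, ForceFieldParams, bond_force_mag
from .system import ParticleSystem, Topology, wrap_positions, write_xyz_frame
from .units import KB, fs_to_internal, ps_to_internal

__all__ = [
    "LangevinParams",
    "Trajectory",
    "compute_forces",
    "potential_energy",
    "kinetic_temperature",
    "run",
    "NeighborList",
]


@dataclass(frozen=True)
class LangevinParams:
    """Integrator settings.

    temperature in K, t_damp in ps (the published damping factor is
    1000 ps; short test runs use ~1 ps so velocities decorrelate within
    the run), dt in fs (default 10 fs), neighbor_skin in Å.
    """

    temperature: float = 300.0
    t_damp: float = 1000.0
    dt: float = 10.0
    n_steps: int = 1000
    seed: int = 0
    sample_every: int = 100
    neighbor_skin: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_damp <= 0:
            raise ValueError("t_damp must be positive (use inf to disable)")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


# ---------------------------------------------------------------------------
# force evaluation
# ---------------------------------------------------------------------------

_SPECIES_INDEX = {PROTEIN: 0, DNA: 1}


def _species_tables(species: np.ndarray, ff: ForceFieldParams):
    """Per-pair sigma / lambda lookup tables indexed by species code."""
    sig = np.array([ff.sigma_P, ff.sigma_D])
    sigma_mat = 0.5 * (sig[:, None] + sig[None, :])
    lambda_mat = np.array([[ff.lambda_PP, ff.lambda_PD],
                           [ff.lambda_PD, ff.lambda_DD]])
    codes = np.array([_SPECIES_INDEX[str(s)] for s in species])
    return codes, sigma_mat, lambda_mat


def _excluded_keys(topo: Topology | None, n: int) -> np.ndarray:
    """Directly bonded (1-2) pairs, encoded as i*n+j with i<j, sorted."""
    if topo is None or len(topo.bonds) == 0:
        return np.empty(0, dtype=np.int64)
    b = np.sort(topo.bonds, axis=1)
    return np.sort(b[:, 0] * n + b[:, 1])


def _all_pair_candidates(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


class NeighborList:
    """Verlet neighbor list over a periodic k-d tree.

    Pairs within r_cut + skin are cached and reused until any bead has
    moved more than skin/2 since the last build, which guarantees the
    cached list still contains every pair inside r_cut.
    """

    def __init__(self, r_cut: float, skin: float, box_edge: float):
        if r_cut + skin >= box_edge / 2.0:
            raise ValueError("r_cut + skin must be below half the box edge")
        self.r_cut = r_cut
        self.skin = skin
        self.box_edge = box_edge
        self._pairs: np.ndarray | None = None
        self._ref_positions: np.ndarray | None = None
        self.n_builds = 0

    def pairs(self, positions: np.ndarray) -> np.ndarray:
        if self._pairs is not None:
            disp = positions - self._ref_positions
            disp -= self.box_edge * np.round(disp / self.box_edge)
            if np.max(np.abs(disp)) < self.skin / 2.0:
                return self._pairs
        wrapped = np.mod(positions, self.box_edge)
        tree = cKDTree(wrapped, boxsize=self.box_edge)
        pairs = tree.query_pairs(self.r_cut + self.skin, output_type="ndarray")
        self._pairs = pairs.astype(np.int64)
        self._ref_positions = positions.copy()
        self.n_builds += 1
        return self._pairs


def _nonbonded_forces(positions, box_edge, pairs, codes, sigma_mat, lambda_mat,
                      ff, excluded, forces, energy=False):
    n = len(positions)
    if len(pairs) and len(excluded):
        keys = pairs[:, 0] * n + pairs[:, 1]
        pairs = pairs[~np.isin(keys, excluded, assume_unique=False)]
    if not len(pairs):
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = positions[i] - positions[j]
    d -= box_edge * np.round(d / box_edge)
    r2 = np.einsum("ij,ij->i", d, d)
    sig = sigma_mat[codes[i], codes[j]]
    lam = lambda_mat[codes[i], codes[j]]
    cut = ff.cutoff_factor * sig
    mask = r2 < cut * cut
    if not np.any(mask):
        return 0.0
    i, j, d, sig, lam = i[mask], j[mask], d[mask], sig[mask], lam[mask]
    r = np.sqrt(r2[mask])
    # Ashbaugh-Hatch force, vectorized over heterogeneous sigma/lambda
    eps = ff.epsilon
    sr6 = (sig / r) ** 6
    flj = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    inner = r <= (2.0 ** (1.0 / 6.0)) * sig
    fmag = np.where(inner, flj, lam * flj)
    fvec = (fmag / r)[:, None] * d
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    if energy:
        ulj = 4.0 * eps * (sr6 * sr6 - sr6)
        u = np.where(inner, ulj + (1.0 - lam) * eps, lam * ulj)
        return float(np.sum(u))
    return 0.0


def _bonded_forces(positions, box_edge, topo, ff, forces, energy=False):
    e = 0.0
    if topo is None:
        return e
    if len(topo.bonds):
        i, j = topo.bonds[:, 0], topo.bonds[:, 1]
        d = positions[i] - positions[j]
        d -= box_edge * np.round(d / box_edge)
        r = np.linalg.norm(d, axis=1)
        fmag = bond_force_mag(r, ff)
        fvec = (fmag / r)[:, None] * d
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)
        if energy:
            e += float(np.sum(ff.K_b * (r - ff.r0) ** 2))
    if len(topo.angles) and ff.K_theta > 0:
        ia, ja, ka = topo.angles[:, 0], topo.angles[:, 1], topo.angles[:, 2]
        a = positions[ia] - positions[ja]
        b = positions[ka] - positions[ja]
        a -= box_edge * np.round(a / box_edge)
        b -= box_edge * np.round(b / box_edge)
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        c = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)
        theta = np.arccos(c)
        sin = np.sqrt(np.maximum(1.0 - c * c, 0.0))
        # 2K(theta-theta0)/sin(theta) -> -2K smoothly as theta -> pi
        factor = np.where(sin > 1e-8,
                          2.0 * ff.K_theta * (theta - ff.theta0) /
                          np.maximum(sin, 1e-8),
                          -2.0 * ff.K_theta)
        fi = factor[:, None] * (b / (na * nb)[:, None] - (c / na ** 2)[:, None] * a)
        fk = factor[:, None] * (a / (na * nb)[:, None] - (c / nb ** 2)[:, None] * b)
        np.add.at(forces, ia, fi)
        np.add.at(forces, ka, fk)
        np.add.at(forces, ja, -(fi + fk))
        if energy:
            e += float(np.sum(ff.K_theta * (theta - ff.theta0) ** 2))
    return e


def compute_forces(positions: np.ndarray, species: np.ndarray, box_edge: float,
                   ff: ForceFieldParams, topo: Topology | None = None,
                   neighbor: NeighborList | None = None,
                   return_energy: bool = False):
    """Total forces (kcal/mol/Å) on every bead; optionally the energy.

    ``neighbor=None`` evaluates all pairs directly (the correctness
    oracle); with a :class:`NeighborList` the result is identical to
    floating-point roundoff because the list is guaranteed complete
    inside the cutoff.
    """
    n = len(positions)
    forces = np.zeros((n, 3))
    codes, sigma_mat, lambda_mat = _species_tables(species, ff)
    excluded = _excluded_keys(topo, n)
    if neighbor is None:
        pairs = _all_pair_candidates(n)
    else:
        pairs = neighbor.pairs(positions)
    e_nb = _nonbonded_forces(positions, box_edge, pairs, codes, sigma_mat,
                             lambda_mat, ff, excluded, forces,
                             energy=return_energy)
    e_b = _bonded_forces(positions, box_edge, topo, ff, forces,
                         energy=return_energy)
    if return_energy:
        return forces, e_nb + e_b
    return forces


def potential_energy(system: ParticleSystem, topo: Topology | None,
                     ff: ForceFieldParams) -> float:
    _, e = compute_forces(system.positions, system.species, system.box_edge,
                          ff, topo, return_energy=True)
    return e


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous equipartition temperature T = sum m v^2 / (3 N kB)."""
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if len(masses) == 0:
        raise ValueError("need at least one particle")
    twice_ke = float(np.sum(masses[:, None] * velocities ** 2))
    return twice_ke / (3.0 * len(masses) * KB)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered frames of a run.

    positions are wrapped; ``unwrapped()`` restores continuous
    coordinates from the stored image counts.  times are in fs and
    strictly increasing.
    """

    times_fs: np.ndarray
    positions: np.ndarray   # (F, N, 3) wrapped
    images: np.ndarray      # (F, N, 3) int
    box_edge: float
    species: np.ndarray
    masses: np.ndarray
    velocities: np.ndarray | None = None   # (F, N, 3) internal units
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_fs = np.asarray(self.times_fs, dtype=float)
        if len(self.times_fs) > 1 and np.any(np.diff(self.times_fs) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times_fs)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box_edge

    def frame(self, k: int) -> ParticleSystem:
        vel = self.velocities[k] if self.velocities is not None \
            else np.zeros_like(self.positions[k])
        return ParticleSystem(positions=self.positions[k].copy(),
                              velocities=vel.copy(), species=self.species,
                              masses=self.masses, box_edge=self.box_edge,
                              images=self.images[k].copy())

    # -- persistence -------------------------------------------------------

    def save_npz(self, path) -> None:
        """Compact binary frame store (NumPy .npz); bit-exact round trip."""
        np.savez_compressed(
            path, times_fs=self.times_fs, positions=self.positions,
            images=self.images, box_edge=self.box_edge,
            species=self.species.astype("U8"), masses=self.masses,
            has_velocities=self.velocities is not None,
            velocities=(self.velocities if self.velocities is not None
                        else np.zeros(0)),
        )

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        d = np.load(path, allow_pickle=False)
        vel = d["velocities"] if bool(d["has_velocities"]) else None
        return cls(times_fs=d["times_fs"], positions=d["positions"],
                   images=d["images"], box_edge=float(d["box_edge"]),
                   species=d["species"], masses=d["masses"], velocities=vel)

    def write_xyz(self, path) -> None:
        """Plain-text extended XYZ with image-count columns."""
        with open(path, "w") as fh:
            for k in range(self.n_frames):
                write_xyz_frame(fh, self.frame(k), comment=f"time_fs={self.times_fs[k]}")

    @classmethod
    def read_xyz(cls, path, masses=None, dt_fs: float | None = None) -> "Trajectory":
        from .forcefield import ForceFieldParams
        ff = ForceFieldParams()
        times, frames, images_all, species = [], [], [], None
        with open(path) as fh:
            while True:
                line = fh.readline()
                if not line.strip():
                    break
                n = int(line)
                header = fh.readline()
                box = float(header.split('"')[1].split()[0])
                t = None
                for tok in header.split():
                    if tok.startswith("time_fs="):
                        t = float(tok.split("=")[1])
                times.append(t if t is not None else float(len(times)))
                sp, pos, im = [], [], []
                for _ in range(n):
                    parts = fh.readline().split()
                    sp.append(PROTEIN if parts[0] == "P" else DNA)
                    pos.append([float(x) for x in parts[1:4]])
                    im.append([int(x) for x in parts[4:7]])
                frames.append(pos)
                images_all.append(im)
                species = np.array(sp)
        positions = np.array(frames)
        if masses is None:
            masses = np.where(species == PROTEIN, ff.mass_P, ff.mass_D)
        return cls(times_fs=np.array(times), positions=positions,
                   images=np.array(images_all, dtype=np.int64), box_edge=box,
                   species=species, masses=np.asarray(masses, dtype=float))


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def run(system: ParticleSystem, topo: Topology | None, ff: ForceFieldParams,
        lp: LangevinParams, use_neighbor_list: bool = True,
        log_every: int = 0, log=print) -> Trajectory:
    """Integrate Langevin dynamics and return the sampled trajectory.

    Deterministic for a fixed seed.  Raises if any bead moves more than
    half a box edge in one step (a symptom of overlapping initial
    coordinates or an oversized time step).
    """
    n = system.n_beads
    box = system.box_edge
    dt = fs_to_internal(lp.dt)
    kt = KB * lp.temperature
    masses = system.masses[:, None]

    thermostat = np.isfinite(lp.t_damp)
    if thermostat:
        tdamp = ps_to_internal(lp.t_damp)
        c1 = np.exp(-dt / tdamp)
        c2 = np.sqrt((1.0 - c1 * c1) * kt / system.masses)[:, None]
    rng = np.random.default_rng(lp.seed)

    neighbor = None
    if use_neighbor_list:
        r_cut = ff.max_cutoff()
        if r_cut + lp.neighbor_skin < box / 2.0:
            neighbor = NeighborList(r_cut, lp.neighbor_skin, box)

    x = system.unwrapped().astype(float)
    v = system.velocities.astype(float).copy()

    def forces_of(pos):
        return compute_forces(pos, system.species, box, ff, topo, neighbor)

    f = forces_of(x)

    times, frames, images_all, vels = [], [], [], []

    def record(step):
        wrapped, images = wrap_positions(x, box)
        times.append(step * lp.dt)
        frames.append(wrapped)
        images_all.append(images)
        vels.append(v.copy())

    record(0)
    for step in range(1, lp.n_steps + 1):
        v += 0.5 * dt * f / masses
        x_old = x.copy()
        x += 0.5 * dt * v
        if thermostat:
            v = c1 * v + c2 * rng.standard_normal((n, 3))
        x += 0.5 * dt * v
        if np.max(np.abs(x - x_old)) > box / 2.0:
            raise RuntimeError(
                f"bead moved more than half the box in step {step}: "
                "reduce the time step or fix overlapping initial coordinates"
            )
        f = forces_of(x)
        v += 0.5 * dt * f / masses
        if step % lp.sample_every == 0:
            record(step)
        if log_every and step % log_every == 0:
            log(f"step {step}  T_kin={kinetic_temperature(v, system.masses):.1f} K")

    return Trajectory(
        times_fs=np.array(times),
        positions=np.array(frames),
        images=np.array(images_all, dtype=np.int64),
        box_edge=box, species=system.species, masses=system.masses,
        velocities=np.array(vels),
        metadata={"langevin": dataclasses.asdict(lp)},
    )
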