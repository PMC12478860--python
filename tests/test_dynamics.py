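"""Integrator physics: thermostat, fluctuation-dissipation, conservation laws,
neighbor-list correctness, trajectory IO."""

import numpy as np
import pytest

from pdcondensate.dynamics import (LangevinParams, NeighborList, Trajectory,
                                   compute_forces, kinetic_temperature,
                                   potential_energy, run)
from pdcondensate.forcefield import DNA, PROTEIN, ForceFieldParams, R_MIN_FACTOR
from pdcondensate.system import ParticleSystem, Topology, build_mixture
from pdcondensate.units import KB, ps_to_internal


def _free_gas(n, box, mass, seed=0):
    rng = np.random.default_rng(seed)
    return ParticleSystem(positions=rng.uniform(0, box, (n, 3)),
                          velocities=np.zeros((n, 3)),
                          species=np.array([PROTEIN] * n),
                          masses=np.full(n, mass), box_edge=box)


def _dimer(stretch=0.7, box=200.0):
    pos = np.array([[100.0, 100, 100], [100 + 5.5 + stretch, 100, 100]])
    system = ParticleSystem(positions=pos, velocities=np.zeros((2, 3)),
                            species=np.array([DNA, DNA]),
                            masses=np.full(2, 500.0), box_edge=box)
    topo = Topology(molecules=[(0, DNA, np.array([0, 1]))], bonds=[[0, 1]],
                    angles=np.empty((0, 3)), chain_length=2)
    return system, topo


class TestKineticTemperature:
    def test_zero_velocities(self):
        assert kinetic_temperature(np.zeros((5, 3)), np.full(5, 500.0)) == 0.0

    def test_single_particle_inversion(self):
        # m v^2 = 3 kB T  ->  exactly 300 K
        m = 5000.0
        v = np.sqrt(3 * KB * 300.0 / m)
        assert kinetic_temperature(np.array([[v, 0.0, 0.0]]),
                                   np.array([m])) == pytest.approx(300.0)

    def test_maxwell_boltzmann_sample(self, rng):
        n, m, t = 100_000, 500.0, 300.0
        v = rng.normal(0.0, np.sqrt(KB * t / m), size=(n, 3))
        assert kinetic_temperature(v, np.full(n, m)) == pytest.approx(
            t, rel=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kinetic_temperature(np.zeros((0, 3)), np.zeros(0))


class TestLangevinIntegration:
    def test_einstein_relation_free_particles(self):
        """Long-time MSD slope gives D = kB T t_damp / m for a free gas."""
        ffree = ForceFieldParams(epsilon=1e-12)
        system = _free_gas(1000, 5000.0, mass=500.0, seed=0)
        lp = LangevinParams(temperature=300.0, t_damp=1.0, dt=10.0,
                            n_steps=4000, seed=3, sample_every=100)
        traj = run(system, None, ffree, lp)
        disp = traj.unwrapped()[-1] - traj.unwrapped()[20]
        t_int = (traj.times_fs[-1] - traj.times_fs[20]) / 48.8882
        d_emp = np.mean(np.sum(disp ** 2, axis=1)) / (6 * t_int)
        d_th = KB * 300.0 * ps_to_internal(1.0) / 500.0
        assert d_emp == pytest.approx(d_th, rel=0.05)

    def test_thermostat_equipartition_bonded_system(self, ff):
        """Bonded + nonbonded mixture thermalizes to 300 K (test damping)."""
        system, topo = build_mixture(8, 20, 40, 700.0,
                                     placement_radius=170.0, seed=4)
        lp = LangevinParams(temperature=300.0, t_damp=1.0, dt=10.0,
                            n_steps=4000, seed=5, sample_every=50)
        traj = run(system, topo, ff, lp, use_neighbor_list=False)
        temps = [kinetic_temperature(traj.velocities[k], traj.masses)
                 for k in range(traj.n_frames // 4, traj.n_frames)]
        assert np.mean(temps) == pytest.approx(300.0, rel=0.03)

    def test_energy_conservation_thermostat_off(self, ff):
        """Velocity-Verlet limit: harmonic dimer, no secular energy drift."""
        system, topo = _dimer()
        lp = LangevinParams(t_damp=np.inf, dt=10.0, n_steps=10_000, seed=0,
                            sample_every=10)
        traj = run(system, topo, ff, lp, use_neighbor_list=False)
        energies = []
        for k in range(traj.n_frames):
            fr = traj.frame(k)
            pe = potential_energy(fr, topo, ff)
            ke = 0.5 * np.sum(fr.masses[:, None] * traj.velocities[k] ** 2)
            energies.append(pe + ke)
        energies = np.asarray(energies)
        tail = len(energies) // 10
        drift = abs(energies[-tail:].mean() - energies[:tail].mean())
        assert drift / abs(energies.mean()) < 1e-4

    def test_stationary_at_pair_minimum(self):
        """Two repulsive-only beads at the potential minimum stay put."""
        ff = ForceFieldParams()
        r_min = R_MIN_FACTOR * ff.sigma_P
        pos = np.array([[100.0, 100, 100], [100 + r_min, 100, 100]])
        system = ParticleSystem(positions=pos, velocities=np.zeros((2, 3)),
                                species=np.array([PROTEIN, PROTEIN]),
                                masses=np.full(2, ff.mass_P), box_edge=400.0)
        lp = LangevinParams(t_damp=np.inf, dt=10.0, n_steps=200, seed=0,
                            sample_every=50)
        traj = run(system, None, ff, lp, use_neighbor_list=False)
        assert np.allclose(traj.unwrapped()[-1], traj.unwrapped()[0],
                           atol=1e-9)

    def test_momentum_conserved_without_thermostat(self, ff):
        system, topo = build_mixture(6, 10, 20, 700.0,
                                     placement_radius=170.0, seed=7)
        rng = np.random.default_rng(0)
        v0 = rng.normal(0, 0.005, system.velocities.shape)
        v0 -= (system.masses[:, None] * v0).sum(0) / system.masses.sum()
        system.velocities = v0
        lp = LangevinParams(t_damp=np.inf, dt=10.0, n_steps=2000, seed=0,
                            sample_every=2000)
        traj = run(system, topo, ff, lp, use_neighbor_list=False)
        p_final = (traj.masses[:, None] * traj.velocities[-1]).sum(0)
        p_scale = np.sum(traj.masses * np.linalg.norm(traj.velocities[-1],
                                                      axis=1))
        assert np.all(np.abs(p_final) / p_scale < 1e-8)

    def test_deterministic_for_seed(self, ff):
        system, topo = build_mixture(5, 10, 20, 700.0,
                                     placement_radius=170.0, seed=1)
        lp = LangevinParams(t_damp=1.0, dt=10.0, n_steps=300, seed=9,
                            sample_every=100)
        t1 = run(system, topo, ff, lp, use_neighbor_list=False)
        system2, topo2 = build_mixture(5, 10, 20, 700.0,
                                       placement_radius=170.0, seed=1)
        t2 = run(system2, topo2, ff, lp, use_neighbor_list=False)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.velocities, t2.velocities)

    def test_blowup_aborts_with_diagnostic(self):
        ff = ForceFieldParams()
        pos = np.array([[100.0, 100, 100], [101.0, 100, 100]])  # deep overlap
        system = ParticleSystem(positions=pos, velocities=np.zeros((2, 3)),
                                species=np.array([PROTEIN, PROTEIN]),
                                masses=np.full(2, ff.mass_P), box_edge=400.0)
        lp = LangevinParams(t_damp=np.inf, dt=10.0, n_steps=50, seed=0,
                            sample_every=10)
        with pytest.raises(RuntimeError, match="half the box"):
            run(system, None, ff, lp, use_neighbor_list=False)


class TestNeighborList:
    def test_equivalent_to_all_pairs(self, ff):
        """Verlet-list forces match the all-pairs oracle to 1e-10."""
        rng = np.random.default_rng(2024)
        box = 1000.0
        species = np.array([PROTEIN] * 100 + [DNA] * 100)
        for _ in range(50):
            pos = rng.uniform(0, box, (200, 3))
            f_ref = compute_forces(pos, species, box, ff)
            nl = NeighborList(ff.max_cutoff(), 10.0, box)
            f_nl = compute_forces(pos, species, box, ff, neighbor=nl)
            # random configs contain deep overlaps with ~1e7 forces, so
            # the 1e-10 agreement is relative to the local force scale
            scale = np.maximum(np.abs(f_ref), 1.0)
            assert np.max(np.abs(f_ref - f_nl) / scale) < 1e-10

    def test_list_reused_until_skin_exceeded(self, ff):
        rng = np.random.default_rng(1)
        box = 1000.0
        pos = rng.uniform(0, box, (50, 3))
        nl = NeighborList(ff.max_cutoff(), 20.0, box)
        nl.pairs(pos)
        nl.pairs(pos + 1.0)     # below skin/2 = 10 -> no rebuild
        assert nl.n_builds == 1
        nl.pairs(pos + 15.0)    # beyond skin/2 -> rebuild
        assert nl.n_builds == 2

    def test_oversized_cutoff_rejected(self):
        with pytest.raises(ValueError):
            NeighborList(200.0, 20.0, 400.0)


class TestTrajectoryIO:
    def _make_traj(self, seed=0):
        system, topo = build_mixture(5, 10, 20, 700.0,
                                     placement_radius=170.0, seed=seed)
        lp = LangevinParams(t_damp=1.0, dt=10.0, n_steps=100, seed=seed,
                            sample_every=50)
        return run(system, topo, ForceFieldParams(), lp,
                   use_neighbor_list=False)

    def test_npz_round_trip_bit_exact(self, tmp_path):
        traj = self._make_traj()
        path = tmp_path / "t.npz"
        traj.save_npz(path)
        back = Trajectory.load_npz(path)
        assert np.array_equal(back.positions, traj.positions)
        assert np.array_equal(back.images, traj.images)
        assert np.array_equal(back.velocities, traj.velocities)

    def test_xyz_round_trip_positions(self, tmp_path):
        traj = self._make_traj(seed=2)
        path = tmp_path / "t.xyz"
        traj.write_xyz(path)
        back = Trajectory.read_xyz(path)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.positions, traj.positions, atol=5e-6)
        assert np.array_equal(back.images, traj.images)
        assert np.array_equal(back.species, traj.species)

    def test_times_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            Trajectory(times_fs=np.array([0.0, 0.0]),
                       positions=np.zeros((2, 1, 3)),
                       images=np.zeros((2, 1, 3), dtype=int),
                       box_edge=10.0, species=np.array([PROTEIN]),
                       masses=np.array([5000.0]))
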