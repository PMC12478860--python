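"""Clustering vs a union-find oracle, composition fractions, block averages."""

import numpy as np
import pytest

from pdcondensate.condensate import (BlockScheme, block_average,
                                     bound_protein_fraction, cluster_beads,
                                     default_bound_cutoff,
                                     default_cluster_cutoff,
                                     largest_cluster_fractions)
from pdcondensate.forcefield import DNA, PROTEIN, ForceFieldParams
from pdcondensate.system import Topology


def _union_find_oracle(positions, box, cutoff):
    """Brute-force all-pairs union-find clustering (independent oracle)."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            d -= box * np.round(d / box)
            if np.dot(d, d) <= cutoff * cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def _as_partition(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(map(tuple, groups.values()))


class TestClusterBeads:
    def test_default_cutoff_is_published_criterion(self, ff):
        assert default_cluster_cutoff(ff) == pytest.approx(41.25)
        assert default_bound_cutoff(ff) == pytest.approx(55.0)

    def test_pair_below_and_above_cutoff(self):
        near = np.array([[0.0, 0, 0], [41.0, 0, 0]])
        far = np.array([[0.0, 0, 0], [42.0, 0, 0]])
        assert cluster_beads(near, 2000.0).n_clusters == 1
        assert cluster_beads(far, 2000.0).n_clusters == 2

    def test_matches_union_find_oracle(self, rng):
        box = 300.0
        pos = rng.uniform(0, box, (500, 3))
        cutoff = 41.25
        labels = cluster_beads(pos, box, cutoff).labels
        oracle = _union_find_oracle(pos, box, cutoff)
        assert _as_partition(labels) == _as_partition(oracle)

    def test_connects_across_periodic_boundary(self):
        pos = np.array([[1.0, 50, 50], [299.0, 50, 50]])
        assert cluster_beads(pos, 300.0, 41.25).n_clusters == 1

    def test_translation_and_permutation_invariance(self, rng):
        box = 400.0
        pos = rng.uniform(0, box, (120, 3))
        base = _as_partition(cluster_beads(pos, box).labels)
        shifted = np.mod(pos + np.array([373.3, 41.0, 999.2]), box)
        assert _as_partition(cluster_beads(shifted, box).labels) == base
        perm = rng.permutation(120)
        perm_part = _as_partition(cluster_beads(pos[perm], box).labels)
        unperm = sorted(tuple(sorted(perm[list(g)])) for g in perm_part)
        assert [tuple(sorted(g)) for g in unperm] == base

    def test_oversized_cutoff_rejected(self, rng):
        with pytest.raises(ValueError, match="half the box"):
            cluster_beads(rng.uniform(0, 50, (10, 3)), 50.0, cutoff=30.0)

    def test_per_pair_mode_links_touching_proteins(self, ff):
        # two proteins at their LJ minimum (~56 Å): linked only per-pair
        pos = np.array([[0.0, 0, 0], [56.0, 0, 0]])
        species = np.array([PROTEIN, PROTEIN])
        assert cluster_beads(pos, 2000.0).n_clusters == 2
        per_pair = cluster_beads(pos, 2000.0, per_pair=True,
                                 species=species, ff=ff)
        assert per_pair.n_clusters == 1


def _topology(n_protein, chain_length, n_chains):
    molecules = [(i, PROTEIN, np.array([i])) for i in range(n_protein)]
    bonds = []
    for c in range(n_chains):
        start = n_protein + c * chain_length
        idx = np.arange(start, start + chain_length)
        molecules.append((n_protein + c, DNA, idx))
        bonds.append(np.column_stack([idx[:-1], idx[1:]]))
    return Topology(molecules=molecules,
                    bonds=np.concatenate(bonds) if bonds
                    else np.empty((0, 2)),
                    angles=np.empty((0, 3)), chain_length=chain_length)


class TestLargestClusterFractions:
    def test_everything_one_cluster(self, rng):
        n_p, L, n_c = 20, 10, 2
        pos = rng.uniform(0, 30.0, (n_p + L * n_c, 3))
        species = np.array([PROTEIN] * n_p + [DNA] * (L * n_c))
        topo = _topology(n_p, L, n_c)
        cl = cluster_beads(pos, 2000.0)
        f_p, f_d = largest_cluster_fractions(cl, topo, species)
        assert (f_p, f_d) == (1.0, 1.0)

    def test_no_contacts_gives_single_molecule_share(self):
        # 4 isolated proteins: the largest cluster is one bead
        pos = np.array([[0.0, 0, 0], [500.0, 0, 0], [0, 500.0, 0],
                        [0, 0, 500.0]])
        species = np.array([PROTEIN] * 4)
        topo = _topology(4, 1, 0)
        topo.molecules = topo.molecules[:4]
        cl = cluster_beads(pos, 2000.0)
        f_p, _ = largest_cluster_fractions(cl, topo, species)
        assert f_p == pytest.approx(0.25)

    def test_any_bead_rule_counts_whole_chain(self):
        """One chain touching the protein cluster by one bead -> f_D = 0.05."""
        n_p, L, n_c = 100, 250, 20
        rng = np.random.default_rng(0)
        # compact protein blob at the center
        prot = 1000.0 + rng.uniform(-20, 20, (n_p, 3))
        chains = []
        for c in range(n_c):
            rod = np.zeros((L, 3))
            rod[:, 0] = np.arange(L) * 5.5
            if c == 0:
                # first bead within the cutoff of the blob
                rod += prot[0] + np.array([30.0, 0, 0])
            else:
                rod += np.array([3000.0 + 2000.0 * c, 500.0 * c, 0.0])
            chains.append(rod)
        pos = np.concatenate([prot] + chains)
        box = 1e6  # effectively open
        species = np.array([PROTEIN] * n_p + [DNA] * (L * n_c))
        topo = _topology(n_p, L, n_c)
        cl = cluster_beads(pos, box)
        f_p, f_d = largest_cluster_fractions(cl, topo, species)
        assert f_p == 1.0
        assert f_d == pytest.approx(0.05)

    def test_fractions_non_decreasing_in_cutoff(self, rng):
        """Growing the cutoff can only add members to a dominant cluster.

        (With several same-sized competing clusters the *identity* of the
        largest can switch between cutoffs, so the monotonicity statement
        applies to configurations with one dominant condensate, which is
        the regime the composition analysis targets.)
        """
        box = 1000.0
        n_p, L, n_c = 40, 10, 4
        # dominant blob: half the proteins and one chain packed centrally
        blob_p = 500.0 + rng.uniform(-25, 25, (20, 3))
        gas_p = rng.uniform(0, box, (20, 3))
        chain0 = 500.0 + np.column_stack([np.arange(L) * 5.5,
                                          np.zeros(L), np.zeros(L)])
        gas_d = rng.uniform(0, box, ((n_c - 1) * L, 3))
        pos = np.concatenate([blob_p, gas_p, chain0, gas_d])
        species = np.array([PROTEIN] * n_p + [DNA] * (L * n_c))
        topo = _topology(n_p, L, n_c)
        prev_fp, prev_fd = 0.0, 0.0
        for cutoff in (10.0, 30.0, 60.0, 120.0):
            cl = cluster_beads(pos, box, cutoff)
            f_p, f_d = largest_cluster_fractions(cl, topo, species)
            assert f_p >= prev_fp - 1e-12
            assert f_d >= prev_fd - 1e-12
            prev_fp, prev_fd = f_p, f_d


class TestBoundProteinFraction:
    def test_distance_threshold_is_sigma_sum(self):
        for d, expected in ((54.9, 1.0), (55.1, 0.0)):
            pos = np.array([[0.0, 0, 0], [d, 0, 0]])
            species = np.array([PROTEIN, DNA])
            assert bound_protein_fraction(pos, species, 2000.0) == expected

    def test_no_dna_gives_zero(self):
        pos = np.array([[0.0, 0, 0]])
        assert bound_protein_fraction(pos, np.array([PROTEIN]), 2000.0) == 0.0

    def test_matches_brute_force(self, rng):
        box = 400.0
        n = 150
        pos = rng.uniform(0, box, (n, 3))
        species = np.array([PROTEIN] * 70 + [DNA] * 80)
        got = bound_protein_fraction(pos, species, box)
        # direct all-pairs check
        cutoff = 55.0
        bound = 0
        for i in range(70):
            d = pos[i] - pos[70:]
            d -= box * np.round(d / box)
            if np.min(np.einsum("ij,ij->i", d, d)) <= cutoff ** 2:
                bound += 1
        assert got == pytest.approx(bound / 70)

    def test_restriction_mask(self):
        pos = np.array([[0.0, 0, 0], [500.0, 0, 0], [30.0, 0, 0]])
        species = np.array([PROTEIN, PROTEIN, DNA])
        mask = np.array([True, False, False])
        assert bound_protein_fraction(pos, species, 2000.0,
                                      restrict_to=mask) == 1.0


class TestBlockAverage:
    def test_published_scheme_on_block_means(self):
        # one frame per block: [1..5], discard the first
        mean, stderr = block_average([1, 2, 3, 4, 5], BlockScheme())
        assert mean == pytest.approx(3.5)
        assert stderr == pytest.approx(np.std([2, 3, 4, 5], ddof=1) / 2.0)
        assert stderr == pytest.approx(0.6455, abs=1e-4)

    def test_constant_series(self):
        mean, stderr = block_average(np.full(100, 7.25), BlockScheme())
        assert (mean, stderr) == (7.25, 0.0)

    def test_matches_direct_recomputation(self, rng):
        series = rng.standard_normal(103)   # exercises remainder truncation
        scheme = BlockScheme(n_blocks=5, n_discard=1)
        mean, stderr = block_average(series, scheme)
        block_len = 103 // 5
        blocks = series[: block_len * 5].reshape(5, block_len)
        kept = blocks.mean(axis=1)[1:]
        assert mean == pytest.approx(kept.mean())
        assert stderr == pytest.approx(kept.std(ddof=1) / np.sqrt(4))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0], BlockScheme())

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            BlockScheme(n_blocks=5, n_discard=5)


class TestCondensedRegimeDominance:
    def test_largest_cluster_dominates_under_strong_homotypic(self):
        """Strong lambda_PP: the dense droplet stays the dominant cluster."""
        from pdcondensate.dynamics import LangevinParams, run
        from pdcondensate.system import build_mixture
        ff = ForceFieldParams(lambda_PP=4.0, lambda_PD=0.3)
        system, topo = build_mixture(48, 12, 48, box_edge=700.0,
                                     placement_radius=160.0, seed=8, ff=ff)
        lp = LangevinParams(temperature=300.0, t_damp=1.0, dt=10.0,
                            n_steps=1500, seed=8, sample_every=500)
        traj = run(system, topo, ff, lp)
        pos = traj.positions[-1]
        cl = cluster_beads(pos, traj.box_edge, per_pair=True,
                           species=traj.species, ff=ff)
        f_p, _ = largest_cluster_fractions(cl, topo, traj.species)
        assert f_p > 0.5
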