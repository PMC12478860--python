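"""Cluster identification and condensate composition analysis.

A condensate is operationalized as a distance-connected cluster: any two
beads closer than the cutoff (default 1.5 sigma_PD = 41.25 Å) under the
minimum-image convention belong to the same cluster.  The largest cluster
is taken as the dense phase.  Composition is reported as

    f_P = N_P^cluster / N_P^total      (protein beads in the cluster)
    f_D = N_D^cluster / N_D^total      (DNA beads of chains touching it)

where a DNA chain counts wholly as part of the cluster as soon as any one
of its beads is in contact with it.

Time series are summarized with the block-averaging protocol: the series
is split into equal blocks (default five), the first block is discarded as
equilibration, and the mean and standard error are computed from the
remaining block means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .forcefield import DNA, PROTEIN, ForceFieldParams

__all__ = [
    "ClusterResult",
    "BlockScheme",
    "default_cluster_cutoff",
    "default_bound_cutoff",
    "cluster_beads",
    "largest_cluster_fractions",
    "bound_protein_fraction",
    "block_average",
]


@dataclass(frozen=True)
class BlockScheme:
    """Equal-block averaging scheme: n_blocks blocks, first n_discard dropped."""

    n_blocks: int = 5
    n_discard: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least two blocks")
        if not 0 <= self.n_discard < self.n_blocks:
            raise ValueError("n_discard must be smaller than n_blocks")


@dataclass
class ClusterResult:
    """Per-bead cluster labels plus largest-cluster composition."""

    labels: np.ndarray
    largest_id: int = -1
    f_P: float = float("nan")
    f_D: float = float("nan")
    size_distribution: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)


def default_cluster_cutoff(ff: ForceFieldParams | None = None) -> float:
    """1.5 sigma_PD, the published same-cluster distance criterion (Å)."""
    if ff is None:
        ff = ForceFieldParams()
    return 1.5 * ff.sigma_PD


def default_bound_cutoff(ff: ForceFieldParams | None = None) -> float:
    """sigma_P + sigma_D, the published DNA-bound protein criterion (Å)."""
    if ff is None:
        ff = ForceFieldParams()
    return ff.sigma_P + ff.sigma_D


def cluster_beads(positions: np.ndarray, box_edge: float,
                  cutoff: float | None = None, *,
                  per_pair: bool = False, species: np.ndarray | None = None,
                  ff: ForceFieldParams | None = None,
                  cutoff_factor: float = 1.5) -> ClusterResult:
    """Connected components of the contact graph under minimum image.

    By default a single cutoff (1.5 sigma_PD) links any two beads.  With
    ``per_pair=True`` the criterion becomes species-resolved,
    ``cutoff_factor * sigma_ij``, which is required to register direct
    protein-protein contacts: the protein bead diameter (50 Å) puts
    touching proteins at ~56 Å, outside the 41.25 Å global cutoff.

    Labels are relabeled deterministically in order of first appearance,
    so the result is invariant to internal ordering details of the graph
    solver.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if per_pair:
        if species is None:
            raise ValueError("per-pair clustering needs the species array")
        if ff is None:
            ff = ForceFieldParams()
        sig = np.array([ff.sigma_P, ff.sigma_D])
        codes = (np.asarray(species) == DNA).astype(int)
        sigma_mat = 0.5 * (sig[:, None] + sig[None, :])
        cutoff = cutoff_factor * float(sigma_mat.max())
    if cutoff is None:
        cutoff = default_cluster_cutoff()
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= box_edge / 2.0:
        raise ValueError("cutoff must be below half the box edge "
                         "(minimum image would be ambiguous)")
    tree = cKDTree(np.mod(positions, box_edge), boxsize=box_edge)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if per_pair and len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = positions[i] - positions[j]
        d -= box_edge * np.round(d / box_edge)
        r = np.linalg.norm(d, axis=1)
        pairs = pairs[r <= cutoff_factor * sigma_mat[codes[i], codes[j]]]
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        adj = sparse.coo_matrix((data, (pairs[:, 0], pairs[:, 1])),
                                shape=(n, n))
        _, raw = connected_components(adj, directed=False)
    else:
        raw = np.arange(n)
    # relabel by order of first appearance
    _, first_idx, inv = np.unique(raw, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_idx))
    labels = order[inv]
    sizes = np.bincount(labels)
    return ClusterResult(labels=labels,
                         size_distribution=dict(zip(*np.unique(sizes,
                                                               return_counts=True))))


def largest_cluster_fractions(cluster: ClusterResult, topo,
                              species: np.ndarray) -> tuple[float, float]:
    """(f_P, f_D) of the largest cluster; fills the fields of ``cluster``.

    Largest is by total bead count (ties broken by smallest label).  A DNA
    chain is counted wholly once any of its beads carries the largest
    label.
    """
    labels = cluster.labels
    sizes = np.bincount(labels)
    largest = int(np.argmax(sizes))
    species = np.asarray(species)
    is_p = species == PROTEIN
    is_d = species == DNA
    n_p_total = int(is_p.sum())
    n_d_total = int(is_d.sum())
    in_cluster = labels == largest

    f_p = float(np.sum(in_cluster & is_p) / n_p_total) if n_p_total else 0.0
    n_d_cluster = 0
    for _, sp, idx in topo.molecules:
        if sp == DNA and np.any(in_cluster[idx]):
            n_d_cluster += len(idx)
    f_d = n_d_cluster / n_d_total if n_d_total else 0.0

    cluster.largest_id = largest
    cluster.f_P = f_p
    cluster.f_D = f_d
    return f_p, f_d


def bound_protein_fraction(positions: np.ndarray, species: np.ndarray,
                           box_edge: float, cutoff: float | None = None,
                           restrict_to: np.ndarray | None = None) -> float:
    """Fraction of proteins within ``cutoff`` of any DNA bead.

    ``cutoff`` defaults to sigma_P + sigma_D = 55 Å.  ``restrict_to`` is an
    optional boolean mask (e.g. largest-cluster membership) limiting which
    proteins enter numerator and denominator; returns 0 when the system
    holds no DNA.
    """
    if cutoff is None:
        cutoff = default_bound_cutoff()
    positions = np.asarray(positions, dtype=float)
    species = np.asarray(species)
    is_p = species == PROTEIN
    if restrict_to is not None:
        is_p = is_p & np.asarray(restrict_to, dtype=bool)
    n_p = int(is_p.sum())
    if n_p == 0:
        raise ValueError("no protein beads to classify")
    dna_pos = positions[species == DNA]
    if len(dna_pos) == 0:
        return 0.0
    tree = cKDTree(np.mod(dna_pos, box_edge), boxsize=box_edge)
    d, _ = tree.query(np.mod(positions[is_p], box_edge), k=1)
    return float(np.sum(d <= cutoff) / n_p)


def block_average(series, scheme: BlockScheme | None = None) -> tuple[float, float]:
    """(mean, stderr) of a time series via equal-block averaging.

    The series is split into ``n_blocks`` equal blocks (remainder frames
    at the end are dropped), the first ``n_discard`` blocks are discarded
    as equilibration, and the result is the mean of block means with
    stderr = sample std of block means / sqrt(kept blocks).
    """
    if scheme is None:
        scheme = BlockScheme()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(series) < scheme.n_blocks:
        raise ValueError(
            f"series of length {len(series)} is shorter than "
            f"{scheme.n_blocks} blocks"
        )
    block_len = len(series) // scheme.n_blocks
    trimmed = series[: block_len * scheme.n_blocks]
    means = trimmed.reshape(scheme.n_blocks, block_len).mean(axis=1)
    kept = means[scheme.n_discard:]
    mean = float(kept.mean())
    if len(kept) < 2:
        return mean, 0.0
    stderr = float(kept.std(ddof=1) / np.sqrt(len(kept)))
    return mean, stderr
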