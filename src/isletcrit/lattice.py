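"""Bond percolation on finite rectangular lattices.

The islet β-cell network is abstracted as a cubic lattice of nodes (cells)
whose nearest-neighbor bonds (gap-junction connections) are each open
independently with a coupling probability ``p``.  Connected clusters of the
open-bond graph are the functional units over which coupling-mediated
suppression acts.  Boundaries are open (non-periodic), mimicking a finite
islet; the default edge length is ``L = 11`` (1331 cells).

For the cubic lattice the bond-percolation threshold is ``p_c ≈ 0.2488``:
above it a single cluster spans the network and the suppression rule acts
network-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LatticeSpec",
    "BondLattice",
    "ClusterSet",
    "build_cubic_lattice",
    "build_lattice",
    "sample_bonds",
    "label_clusters",
    "cluster_size_histogram",
    "largest_cluster_fraction",
    "spanning_probability",
    "estimate_percolation_threshold",
    "ThresholdEstimate",
    "replicate_rng",
    "clusters_to_frame",
]


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """One seeded generator per replicate: the replicate index is folded into
    the seed stream, so sweeps are reproducible point-by-point and can be
    parallelized without sharing generator state."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


@dataclass(frozen=True)
class LatticeSpec:
    """A rectangular node lattice with its full nearest-neighbor bond list.

    ``dims`` are the node counts per axis; ``candidate_bonds`` is the
    ``(B, 2)`` array of unordered node-index pairs (i < j) for all
    nearest-neighbor adjacencies under open boundaries.
    """

    dims: tuple[int, int, int]
    candidate_bonds: np.ndarray = field(repr=False)

    @property
    def node_count(self) -> int:
        lx, ly, lz = self.dims
        return lx * ly * lz

    @property
    def bond_count(self) -> int:
        return len(self.candidate_bonds)

    def face_nodes(self, axis: int, side: int) -> np.ndarray:
        """Node indices on one face of the box (side 0 = low, 1 = high)."""
        lx, ly, lz = self.dims
        coords = np.indices(self.dims).reshape(3, -1)
        sel = coords[axis] == (0 if side == 0 else self.dims[axis] - 1)
        return np.nonzero(sel)[0]


@dataclass(frozen=True)
class BondLattice:
    """A sampled bond configuration: the subset of candidate bonds that are
    open at coupling probability ``p``, reproducible given ``seed``."""

    spec: LatticeSpec
    open_bonds: np.ndarray = field(repr=False)
    p: float
    seed: object


@dataclass(frozen=True)
class ClusterSet:
    """Connected components of an open-bond configuration.

    ``assignment`` maps node index -> cluster id; ``sizes[cid]`` is the node
    count of cluster ``cid``.  Sizes always sum to the node count.
    """

    assignment: np.ndarray = field(repr=False)
    sizes: np.ndarray = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def node_count(self) -> int:
        return len(self.assignment)


def build_lattice(dims: tuple[int, int, int]) -> LatticeSpec:
    """Build a rectangular nearest-neighbor lattice with open boundaries."""
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ValueError(f"lattice dims must be three positive integers, got {dims}")
    lx, ly, lz = dims
    idx = np.arange(lx * ly * lz).reshape(dims)
    pairs = []
    # bonds along each axis between a node and its +1 neighbor
    pairs.append(np.stack([idx[:-1, :, :].ravel(), idx[1:, :, :].ravel()], axis=1))
    pairs.append(np.stack([idx[:, :-1, :].ravel(), idx[:, 1:, :].ravel()], axis=1))
    pairs.append(np.stack([idx[:, :, :-1].ravel(), idx[:, :, 1:].ravel()], axis=1))
    bonds = np.concatenate(pairs, axis=0)
    return LatticeSpec(dims=dims, candidate_bonds=bonds)


def build_cubic_lattice(L: int) -> LatticeSpec:
    """Cubic lattice of edge length ``L`` nodes: ``L**3`` nodes and
    ``3 * L**2 * (L - 1)`` candidate bonds."""
    L = int(L)
    if L < 1:
        raise ValueError(f"L must be a positive integer, got {L}")
    return build_lattice((L, L, L))


def sample_bonds(spec: LatticeSpec, p: float, seed) -> BondLattice:
    """Sample a bond configuration: each candidate bond draws a uniform
    variate on [0, 1) and is open when the variate is <= ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"coupling probability p must lie in [0, 1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(spec.bond_count)
    open_bonds = spec.candidate_bonds[u <= p]
    return BondLattice(spec=spec, open_bonds=open_bonds, p=float(p), seed=seed)


def label_clusters(lattice: BondLattice) -> ClusterSet:
    """Exact connected components of the open-bond graph."""
    n = lattice.spec.node_count
    e = lattice.open_bonds
    if len(e) == 0:
        return ClusterSet(assignment=np.arange(n), sizes=np.ones(n, dtype=np.int64))
    graph = sparse.coo_matrix(
        (np.ones(len(e), dtype=np.int8), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    return ClusterSet(assignment=labels, sizes=sizes.astype(np.int64))


def cluster_size_histogram(clusters: ClusterSet) -> pd.Series:
    """Node density per cluster size: fraction of all nodes that sit in a
    cluster of each size.  Sums to 1."""
    sizes, counts = np.unique(clusters.sizes, return_counts=True)
    density = sizes * counts / clusters.node_count
    return pd.Series(density, index=pd.Index(sizes, name="size"), name="node_fraction")


def largest_cluster_fraction(L: int, p: float, reps: int, seed: int) -> float:
    """Monte-Carlo mean of (largest cluster size) / L**3."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    spec = build_cubic_lattice(L)
    acc = 0.0
    for r in range(reps):
        cs = label_clusters(sample_bonds(spec, p, replicate_rng(seed, r)))
        acc += cs.sizes.max() / spec.node_count
    return acc / reps


def _spans(spec: LatticeSpec, labels: np.ndarray) -> bool:
    """True if one cluster touches two opposite faces of the box (any axis)."""
    for axis in range(3):
        if spec.dims[axis] < 2:
            continue
        lo = np.unique(labels[spec.face_nodes(axis, 0)])
        hi = np.unique(labels[spec.face_nodes(axis, 1)])
        if len(np.intersect1d(lo, hi, assume_unique=True)) > 0:
            return True
    return False


def spanning_probability(L, p: float, reps: int, seed: int) -> float:
    """Fraction of replicate configurations containing a spanning cluster.

    ``L`` may be an integer (cubic lattice) or a 3-tuple of dims.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    spec = build_cubic_lattice(L) if np.isscalar(L) else build_lattice(L)
    hits = 0
    for r in range(reps):
        cs = label_clusters(sample_bonds(spec, p, replicate_rng(seed, r)))
        if _spans(spec, cs.assignment):
            hits += 1
    return hits / reps


@dataclass(frozen=True)
class ThresholdEstimate:
    """Finite-size crossing estimate of the percolation threshold."""

    value: float
    pairwise: dict
    curves: pd.DataFrame
    failed: bool = False


def estimate_percolation_threshold(
    L_list, reps: int, seed: int, p_grid=None
) -> ThresholdEstimate:
    """Estimate the percolation threshold from the crossing of
    spanning-probability curves across system sizes.

    For each size the spanning probability S_L(p) is estimated on ``p_grid``;
    the threshold is the average of pairwise sign-change crossings of
    S_{L2} - S_{L1} (larger systems span less below threshold, more above).
    The default grid brackets the cubic bond-percolation threshold
    (p_c ≈ 0.2488); callers probing other lattices should pass their own grid.
    """
    if len(L_list) < 2:
        raise ValueError("need at least two system sizes")
    if p_grid is None:
        p_grid = np.round(np.arange(0.20, 0.3001, 0.01), 4)
    p_grid = np.asarray(p_grid, dtype=float)
    curves = {}
    for i, L in enumerate(L_list):
        key = L if np.isscalar(L) else tuple(L)
        curves[key] = np.array(
            [spanning_probability(L, p, reps, seed + 1000 * i) for p in p_grid]
        )
    keys = list(curves)
    crossings = {}
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            d = curves[keys[b]] - curves[keys[a]]
            pc = _sign_change_crossing(p_grid, d, curves[keys[a]], curves[keys[b]])
            if pc is not None:
                crossings[(keys[a], keys[b])] = pc
    frame = pd.DataFrame(curves, index=pd.Index(p_grid, name="p"))
    if not crossings:
        # degenerate case: curves never cross strictly (e.g. a 1D chain, where
        # any closed bond disconnects the system and S_L -> 1 only at p = 1)
        allspan = np.all(frame.to_numpy() >= 1.0 - 1e-12, axis=1)
        if allspan.any():
            return ThresholdEstimate(
                value=float(p_grid[np.argmax(allspan)]), pairwise={}, curves=frame
            )
        return ThresholdEstimate(value=float("nan"), pairwise={}, curves=frame, failed=True)
    value = float(np.mean(list(crossings.values())))
    return ThresholdEstimate(value=value, pairwise=crossings, curves=frame)


def _sign_change_crossing(p_grid, d, s_a, s_b):
    """First strict +/- sign change of d = S_b - S_a, linearly interpolated;
    points where both curves are pinned at 0 or 1 carry no information."""
    informative = (np.maximum(s_a, s_b) > 0.02) & (np.minimum(s_a, s_b) < 0.98)
    for i in range(len(d) - 1):
        if not (informative[i] or informative[i + 1]):
            continue
        if d[i] > 0 and d[i + 1] < 0 or d[i] < 0 and d[i + 1] > 0:
            t = d[i] / (d[i] - d[i + 1])
            return float(p_grid[i] + t * (p_grid[i + 1] - p_grid[i]))
        if d[i] != 0 and d[i + 1] == 0 and informative[i + 1]:
            return float(p_grid[i + 1])
    return None


def clusters_to_frame(clusters: ClusterSet, replicate: int = 0) -> pd.DataFrame:
    """Cluster table (replicate, cluster_id, size) for delimited output."""
    cid = np.arange(clusters.n_clusters)
    return pd.DataFrame(
        {"replicate": replicate, "cluster_id": cid, "size": clusters.sizes}
    )
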