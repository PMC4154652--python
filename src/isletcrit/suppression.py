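"""Binomial suppression rule on percolation clusters.

Each cell is intrinsically excitable with probability ``P_exc`` (inexcitable
with ``q = 1 - P_exc``).  Within a coupled cluster of ``n`` cells, if the
fraction of inexcitable cells exceeds a threshold ``Sp``, gap-junction
coupling suppresses the whole cluster; otherwise the whole cluster is active.
The number of inexcitable cells in a cluster is Binomial(n, q), so the
probability the cluster is active is P(X < k) with k the smallest count whose
fraction exceeds Sp.  Network activity is the cluster-size-weighted average
of this probability, and sweeping P_exc at supra-critical coupling produces
the phase transition near P_exc = 1 - Sp.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .lattice import (
    ClusterSet,
    LatticeSpec,
    build_cubic_lattice,
    label_clusters,
    replicate_rng,
    sample_bonds,
)

__all__ = [
    "SuppressionParams",
    "ActivityCurve",
    "ActivitySurface",
    "suppression_count_threshold",
    "cluster_active_probability",
    "active_probability_by_size",
    "network_activity",
    "network_activity_sampled",
    "node_activity_probability_map",
    "sweep_activity",
]


@dataclass(frozen=True)
class SuppressionParams:
    """(P_exc, Sp) pair governing the cluster activity rule.

    ``rule`` selects the suppression convention: "strict" suppresses a
    cluster when the inexcitable fraction is strictly greater than Sp
    (k = floor(n*Sp) + 1); "gte" uses greater-or-equal (shifts k down by one
    exactly when n*Sp is an integer).
    """

    p_exc: float
    sp: float
    rule: str = "strict"

    def __post_init__(self):
        if not 0.0 <= self.p_exc <= 1.0:
            raise ValueError(f"P_exc must lie in [0, 1], got {self.p_exc}")
        if not 0.0 <= self.sp <= 1.0:
            raise ValueError(f"Sp must lie in [0, 1], got {self.sp}")
        if self.rule not in ("strict", "gte"):
            raise ValueError(f"unknown suppression rule {self.rule!r}")

    @property
    def q(self) -> float:
        """Inexcitable fraction, exactly 1 - P_exc."""
        return 1.0 - self.p_exc


def suppression_count_threshold(n: int, sp: float, rule: str = "strict") -> int:
    """Minimal count of inexcitable cells that suppresses a cluster of size n.

    Under the default strict rule this is the smallest integer k with
    k / n > sp, i.e. ``floor(n * sp) + 1``.
    """
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    if not 0.0 <= sp < 1.0:
        raise ValueError(
            f"Sp must lie in [0, 1); a cluster with Sp = 1 is never suppressed (got {sp})"
        )
    if rule == "strict":
        return int(math.floor(n * sp)) + 1
    if rule == "gte":
        return max(int(math.ceil(n * sp)), 1)
    raise ValueError(f"unknown suppression rule {rule!r}")


def cluster_active_probability(
    n: int, q: float, sp: float, rule: str = "strict"
) -> float:
    """Probability a coupled cluster of size n is active: P(X < k) with
    X ~ Binomial(n, q) and k the suppression count threshold."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if sp >= 1.0:
        return 1.0  # never suppressed
    k = suppression_count_threshold(n, sp, rule)
    return float(binom.cdf(k - 1, n, q))


def active_probability_by_size(
    n_max: int, q, sp: float, rule: str = "strict"
) -> np.ndarray:
    """Vectorized table A[n-1, j] = P(cluster of size n active | q_j).

    ``q`` may be scalar or an array of inexcitable fractions; the result has
    shape (n_max, len(q)).  scipy's binomial CDF carries the numerics
    (regularized incomplete beta, stable for large n).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    n = np.arange(1, n_max + 1)
    if sp >= 1.0:
        return np.ones((n_max, q.size))
    if rule == "strict":
        k = np.floor(n * sp).astype(np.int64) + 1
    else:
        k = np.maximum(np.ceil(n * sp).astype(np.int64), 1)
    return binom.cdf(k[:, None] - 1, n[:, None], q[None, :])


def network_activity(clusters: ClusterSet, params: SuppressionParams) -> float:
    """Expected fraction of active cells: the per-cluster active probability
    averaged over clusters, weighted by cluster size."""
    sizes = clusters.sizes
    table = active_probability_by_size(int(sizes.max()), params.q, params.sp, params.rule)
    pr = table[sizes - 1, 0]
    return float(np.sum(sizes * pr) / np.sum(sizes))


def network_activity_sampled(
    clusters: ClusterSet, params: SuppressionParams, rng, n_draws: int = 1
) -> float:
    """Monte-Carlo cross-check of :func:`network_activity`: sample explicit
    excitability labels and apply the all-or-none cluster rule."""
    n = clusters.node_count
    labels = clusters.assignment
    acc = 0.0
    for _ in range(n_draws):
        inexc = rng.random(n) < params.q
        n_inexc = np.bincount(labels, weights=inexc, minlength=clusters.n_clusters)
        frac = n_inexc / clusters.sizes
        suppressed = frac > params.sp if params.rule == "strict" else frac >= params.sp
        acc += np.sum(clusters.sizes[~suppressed]) / n
    return acc / n_draws


def node_activity_probability_map(
    spec: LatticeSpec, p: float, params: SuppressionParams, reps: int, seed: int
) -> np.ndarray:
    """Per-node activity probability: for each node, the across-replicate
    mean of its cluster's active probability (false-color map substrate)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    acc = np.zeros(spec.node_count)
    for r in range(reps):
        cs = label_clusters(sample_bonds(spec, p, replicate_rng(seed, r)))
        table = active_probability_by_size(int(cs.sizes.max()), params.q, params.sp, params.rule)
        acc += table[cs.sizes[cs.assignment] - 1, 0]
    return acc / reps


@dataclass(frozen=True)
class ActivityCurve:
    """Percent-active vs. a control parameter, with Monte-Carlo errors.

    ``mean_pct`` is on the 0–100 scale of the figures; internal computation
    is on [0, 1].
    """

    control_name: str
    control: np.ndarray = field(repr=False)
    mean_pct: np.ndarray = field(repr=False)
    se_pct: np.ndarray = field(repr=False)
    reps: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.control, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ValueError("control grid must be strictly increasing")
        if np.any((self.mean_pct < -1e-9) | (self.mean_pct > 100 + 1e-9)):
            raise ValueError("percent-active must lie in [0, 100]")
        if np.any(np.asarray(self.se_pct) < 0):
            raise ValueError("standard errors must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "control_name": self.control_name,
                "control_value": self.control,
                "mean_pct_active": self.mean_pct,
                "se_pct_active": self.se_pct,
                "reps": self.reps,
            }
        )
        for key in ("L", "Sp", "p", "seed"):
            if key in self.meta:
                df[key] = self.meta[key]
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "control_name": self.control_name,
                "control": list(map(float, self.control)),
                "mean_pct_active": list(map(float, self.mean_pct)),
                "se_pct_active": list(map(float, self.se_pct)),
                "reps": int(self.reps),
                "meta": {k: _jsonable(v) for k, v in self.meta.items()},
            }
        )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


@dataclass(frozen=True)
class ActivitySurface:
    """Mean percent-active over a (p, P_exc) grid with per-point MC errors."""

    p_grid: np.ndarray = field(repr=False)
    pexc_grid: np.ndarray = field(repr=False)
    mean_pct: np.ndarray = field(repr=False)  # shape (len(p_grid), len(pexc_grid))
    se_pct: np.ndarray = field(repr=False)
    reps: int = 0
    meta: dict = field(default_factory=dict)

    def curve_vs_pexc(self, p: float) -> ActivityCurve:
        i = int(np.argmin(np.abs(self.p_grid - p)))
        return ActivityCurve(
            control_name="P_exc",
            control=self.pexc_grid,
            mean_pct=self.mean_pct[i],
            se_pct=self.se_pct[i],
            reps=self.reps,
            meta={**self.meta, "p": float(self.p_grid[i])},
        )

    def curve_vs_p(self, pexc: float) -> ActivityCurve:
        j = int(np.argmin(np.abs(self.pexc_grid - pexc)))
        return ActivityCurve(
            control_name="p",
            control=self.p_grid,
            mean_pct=self.mean_pct[:, j],
            se_pct=self.se_pct[:, j],
            reps=self.reps,
            meta={**self.meta, "P_exc": float(self.pexc_grid[j])},
        )

    def to_frame(self) -> pd.DataFrame:
        pp, ee = np.meshgrid(self.p_grid, self.pexc_grid, indexing="ij")
        return pd.DataFrame(
            {
                "p": pp.ravel(),
                "P_exc": ee.ravel(),
                "mean_pct_active": self.mean_pct.ravel(),
                "se_pct_active": self.se_pct.ravel(),
                "reps": self.reps,
            }
        )


def replicate_size_counts(
    spec: LatticeSpec, p: float, reps: int, seed: int
) -> "np.ndarray":
    """Sparse (reps x node_count) matrix C with C[r, s-1] = number of
    clusters of size s in replicate r.  The cluster decomposition depends
    only on (p, seed), so this matrix is reused across Sp and P_exc."""
    from scipy import sparse as sp_

    rows, cols, vals = [], [], []
    for r in range(reps):
        cs = label_clusters(sample_bonds(spec, p, replicate_rng(seed, r)))
        sizes, counts = np.unique(cs.sizes, return_counts=True)
        rows.extend([r] * len(sizes))
        cols.extend(sizes - 1)
        vals.extend(counts)
    return sp_.csr_matrix(
        (vals, (rows, cols)), shape=(reps, spec.node_count), dtype=float
    )


def activity_from_size_counts(
    counts, pexc_values, sp: float, node_count: int, rule: str = "strict"
) -> np.ndarray:
    """Per-replicate network activity (fraction) for each P_exc value, given
    a replicate-by-size cluster count matrix."""
    pexc_values = np.atleast_1d(np.asarray(pexc_values, dtype=float))
    table = active_probability_by_size(node_count, 1.0 - pexc_values, sp, rule)
    weights = np.arange(1, node_count + 1)[:, None] * table / node_count
    return np.asarray(counts @ weights)


def sweep_activity(
    p_grid,
    pexc_grid,
    sp: float = 0.15,
    L: int = 11,
    reps: int = 500,
    seed: int = 0,
    rule: str = "strict",
) -> ActivitySurface:
    """Mean and standard error of network activity over freshly sampled bond
    configurations for every (p, P_exc) grid point.

    Cluster decompositions are sampled once per (p, replicate); activity is
    then evaluated analytically for every P_exc via the binomial rule, which
    reproduces the protocol of averaging many simulations per grid point.
    """
    p_grid = np.atleast_1d(np.asarray(p_grid, dtype=float))
    pexc_grid = np.atleast_1d(np.asarray(pexc_grid, dtype=float))
    if np.any((p_grid < 0) | (p_grid > 1)) or np.any((pexc_grid < 0) | (pexc_grid > 1)):
        raise ValueError("grids must lie within [0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    spec = build_cubic_lattice(L)
    mean = np.empty((p_grid.size, pexc_grid.size))
    se = np.empty_like(mean)
    for i, p in enumerate(p_grid):
        counts = replicate_size_counts(spec, p, reps, seed + 7919 * i)
        act = activity_from_size_counts(counts, pexc_grid, sp, spec.node_count, rule)
        mean[i] = act.mean(axis=0) * 100.0
        se[i] = act.std(axis=0, ddof=1) / np.sqrt(reps) * 100.0 if reps > 1 else 0.0
    return ActivitySurface(
        p_grid=p_grid,
        pexc_grid=pexc_grid,
        mean_pct=np.clip(mean, 0.0, 100.0),
        se_pct=se,
        reps=reps,
        meta={"L": L, "Sp": sp, "seed": seed, "rule": rule},
    )
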