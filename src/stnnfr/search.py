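"""Stochastic fixed-radius kNN search (STNNfr).

The training set is bounded by the hypersphere S centered at its centroid
with radius r = max distance to the centroid; by construction no neighbor
lies outside S.  For each query, a radius is solved so that the query's
own hypersphere contains a target fraction tau of the training mass under
a spherical-uniform model, and a KD-tree fixed-radius query retrieves the
candidates.  If fewer than k points fall inside, tau escalates through an
ascending schedule ending at 1, whose solved radius d + r covers all of S
by the triangle inequality — so termination with at least k candidates is
guaranteed and the returned neighbors are *exactly* those of a brute-force
scan, in the same order.

Queries are grouped into G concentric rings of equal spherical-uniform
mass; every query in a ring shares the radius solved at the ring's outer
boundary (a conservative choice: containment probability only grows as
the query moves inward), reducing the number of radius equations from m
to at most G per threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import solve_radius

__all__ = [
    "TrainingIndex",
    "ThresholdSchedule",
    "RingPartition",
    "QueryAssignment",
    "NeighborResult",
    "fit_index",
    "ring_radii",
    "tau_schedule",
    "assign_groups",
    "fixed_radius_candidates",
    "top_k_select",
    "knn_search",
]


@dataclass(frozen=True)
class TrainingIndex:
    """Training matrix plus its bounding-sphere summary and KD-tree.

    ``bounding_radius`` is r = max_j ||x_j - centroid||; the hypersphere of
    that radius around the centroid contains every training point.
    """

    data: np.ndarray
    centroid: np.ndarray
    centroid_distances: np.ndarray
    bounding_radius: float
    tree: cKDTree

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ThresholdSchedule:
    """Ascending probability thresholds tau^(1) < ... < tau^(t) = 1."""

    values: tuple

    def __post_init__(self) -> None:
        v = self.values
        if len(v) < 1:
            raise ValueError("schedule must contain at least one threshold")
        if any(not 0.0 < x <= 1.0 for x in v):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("thresholds must be strictly ascending")
        if v[-1] != 1.0:
            raise ValueError("the final threshold must be exactly 1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class QueryAssignment:
    """Per-query centroid distance and ring-group id (G+1 = outside S)."""

    centroid_distances: np.ndarray
    group_ids: np.ndarray


@dataclass(frozen=True)
class NeighborResult:
    """Ordered k-nearest neighbors per query.

    ``indices``/``distances`` are (m, k), rows ascending in (distance,
    training index); ``candidates_found`` is k' (k <= k' <= n), the number
    of candidates captured when the sweep stopped; ``iterations`` counts
    the thresholds tried per query.
    """

    indices: np.ndarray
    distances: np.ndarray
    candidates_found: np.ndarray
    iterations: np.ndarray

    @property
    def n_queries(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def fit_index(training) -> TrainingIndex:
    """Build the training index: centroid, bounding radius, KD-tree.

    The KD-tree is built once and reused across all queries and sweep
    iterations.
    """
    X = np.asarray(training, dtype=np.float64)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("training must be a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("training matrix contains missing or non-finite values")
    centroid = X.mean(axis=0)
    dists = np.linalg.norm(X - centroid, axis=1)
    return TrainingIndex(
        data=X,
        centroid=centroid,
        centroid_distances=dists,
        bounding_radius=float(dists.max()),
        tree=cKDTree(X),
    )


def ring_radii(r: float, p: int, G: int) -> np.ndarray:
    """Boundary radii delta_g = r * (g/G)^(1/p), g = 1..G.

    Each sub-sphere of radius delta_g holds spherical-uniform mass g/G;
    the last boundary is exactly r.
    """
    if G < 1:
        raise ValueError("G must be a positive integer")
    if r <= 0:
        raise ValueError("bounding radius r must be positive")
    delta = r * (np.arange(1, G + 1) / G) ** (1.0 / p)
    delta[-1] = r
    return delta


def tau_schedule(k: int, n: int, t: int = 10) -> ThresholdSchedule:
    """t thresholds evenly spaced from k/n to 1 inclusive.

    k = n (or t = 1) degenerates to the single threshold 1, preserving the
    covering guarantee of the final sweep step.
    """
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")
    if t < 1:
        raise ValueError("t must be at least 1")
    if k == n or t == 1:
        return ThresholdSchedule(values=(1.0,))
    vals = np.linspace(k / n, 1.0, t)
    vals[-1] = 1.0
    return ThresholdSchedule(values=tuple(float(v) for v in vals))


class RingPartition:
    """G concentric rings of equal spherical-uniform mass over [0, r].

    Solved radii are cached per (group, tau), so a full run solves at most
    G x t radius equations regardless of the query count.
    """

    def __init__(self, bounding_radius: float, p: int, G: int):
        self.G = G
        self.p = p
        self.bounding_radius = bounding_radius
        self.boundary_radii = ring_radii(bounding_radius, p, G)
        self.group_radii: dict[tuple[int, float], float] = {}
        self.equations_solved = 0

    def group_radius(self, g: int, tau: float) -> float:
        """Search radius shared by all queries in ring g at threshold tau.

        Solved with the centroid distance pinned to the ring's *outer*
        boundary delta_g — valid for every query in the ring because
        containment probability is non-increasing in the centroid distance.
        """
        if not 1 <= g <= self.G:
            raise ValueError("g must be a ring id in 1..G")
        key = (g, tau)
        if key not in self.group_radii:
            self.group_radii[key] = solve_radius(
                self.p, self.bounding_radius, float(self.boundary_radii[g - 1]), tau
            )
            self.equations_solved += 1
        return self.group_radii[key]


def assign_groups(index: TrainingIndex, queries, partition: RingPartition) -> QueryAssignment:
    """Ring-group id per query; boundaries closed on the right.

    Distance exactly delta_g maps to group g; distance beyond delta_G = r
    maps to the overflow group G+1 (outside the training sphere).
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if Q.shape[1] != index.p:
        raise ValueError("queries must share the training feature dimension")
    d = np.linalg.norm(Q - index.centroid, axis=1)
    groups = np.searchsorted(partition.boundary_radii, d, side="left") + 1
    return QueryAssignment(centroid_distances=d, group_ids=groups)


def fixed_radius_candidates(index: TrainingIndex, query_point, radius: float):
    """All training rows within ``radius`` of the query, with exact distances.

    The KD-tree supplies the candidate set; distances are recomputed
    directly from the data (not taken from tree internals) and filtered,
    so membership equals a linear-scan distance filter.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = np.asarray(query_point, dtype=np.float64)
    idx = np.asarray(sorted(index.tree.query_ball_point(q, radius)), dtype=np.int64)
    if idx.size == 0:
        return idx, np.empty(0, dtype=np.float64)
    dist = np.linalg.norm(index.data[idx] - q, axis=1)
    keep = dist <= radius
    return idx[keep], dist[keep]


def top_k_select(cand_indices, cand_distances, k: int):
    """The k candidates smallest by (distance, training index), fully ordered."""
    idx = np.asarray(cand_indices, dtype=np.int64)
    dist = np.asarray(cand_distances, dtype=np.float64)
    if idx.size < k:
        raise ValueError(f"need at least k={k} candidates, got {idx.size}")
    order = np.lexsort((idx, dist))[:k]
    return idx[order], dist[order]


def knn_search(
    index: TrainingIndex,
    queries,
    k: int,
    G: int = 1,
    schedule: ThresholdSchedule | None = None,
) -> NeighborResult:
    """Exact k-nearest neighbors via the escalating-tau fixed-radius sweep.

    For each query: look up (ring groups 1..G) or solve (overflow group
    G+1, using the query's own centroid distance) the radius at the current
    threshold, retrieve candidates inside it from the KD-tree, and stop as
    soon as at least k are captured; then keep the k smallest by
    (distance, training index).  Returns the same neighbors in the same
    order as ``oracle.brute_force_knn``.
    """
    X = index.data
    n, p = X.shape
    Q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if Q.shape[1] != p:
        raise ValueError("queries must share the training feature dimension")
    if not np.isfinite(Q).all():
        raise ValueError("query matrix contains missing or non-finite values")
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")

    m = Q.shape[0]
    indices = np.empty((m, k), dtype=np.int64)
    distances = np.empty((m, k), dtype=np.float64)
    kprime = np.empty(m, dtype=np.int64)
    iters = np.empty(m, dtype=np.int64)

    if index.bounding_radius == 0.0:
        # all training rows identical: the radius equation is degenerate,
        # every row is equidistant from any query — first k rows win the tie
        dist0 = np.linalg.norm(Q - X[0], axis=1)
        indices[:] = np.arange(k)
        distances[:] = dist0[:, None]
        kprime[:] = n
        iters[:] = 1
        return NeighborResult(indices, distances, kprime, iters)

    if schedule is None:
        schedule = tau_schedule(k, n, 10)

    partition = RingPartition(index.bounding_radius, p, G)
    assignment = assign_groups(index, Q, partition)
    r = index.bounding_radius

    for i in range(m):
        q = Q[i]
        g = int(assignment.group_ids[i])
        d_i = float(assignment.centroid_distances[i])
        cand: list[int] = []
        used = 0
        for it, tau in enumerate(schedule.values, start=1):
            if g <= G:
                radius = partition.group_radius(g, tau)
            else:
                radius = solve_radius(p, r, d_i, tau)
            cand = index.tree.query_ball_point(q, radius)
            used = it
            if len(cand) >= k:
                break
        if len(cand) < k:  # impossible: the final radius d + r covers S
            raise RuntimeError(
                f"threshold schedule exhausted with {len(cand)} < {k} candidates "
                f"for query {i} (d={d_i}, r={r})"
            )
        cand_idx = np.asarray(sorted(cand), dtype=np.int64)
        cand_dist = np.linalg.norm(X[cand_idx] - q, axis=1)
        top_idx, top_dist = top_k_select(cand_idx, cand_dist, k)
        indices[i] = top_idx
        distances[i] = top_dist
        kprime[i] = len(cand)
        iters[i] = used

    return NeighborResult(indices, distances, kprime, iters)
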