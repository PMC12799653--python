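"""Reference implementations used as ground truth.

``brute_force_knn`` is the exhaustive linear-scan comparator: every
query-to-training distance is computed, sorted, and the k smallest kept.
It is deliberately simple and vectorized — the auditable baseline every
equivalence test is judged against.

``mc_containment_estimate`` is a rejection-sampling estimate of the
spherical-uniform containment probability, the stochastic arbiter for the
closed-form geometry.
"""

from __future__ import annotations

import math

import numpy as np

from .search import NeighborResult

__all__ = ["brute_force_knn", "mc_containment_estimate"]


def brute_force_knn(training, queries, k: int) -> NeighborResult:
    """Exact kNN by computing all n*m distances and sorting.

    Ties in distance are broken by ascending training-row index (stable
    sort over rows already in index order), the same rule the fixed-radius
    search applies.  Distances use the same row-wise norm expression as
    the fixed-radius search so orderings are bit-stable across the two
    methods.
    """
    X = np.asarray(training, dtype=np.float64)
    Q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if X.ndim != 2 or Q.ndim != 2:
        raise ValueError("training and queries must be 2-D matrices")
    if X.shape[1] != Q.shape[1]:
        raise ValueError("training and queries must share the feature dimension")
    n = X.shape[0]
    m = Q.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")

    indices = np.empty((m, k), dtype=np.int64)
    distances = np.empty((m, k), dtype=np.float64)
    for i in range(m):
        d = np.linalg.norm(X - Q[i], axis=1)
        order = np.argsort(d, kind="stable")[:k]
        indices[i] = order
        distances[i] = d[order]

    return NeighborResult(
        indices=indices,
        distances=distances,
        candidates_found=np.full(m, n, dtype=np.int64),
        iterations=np.ones(m, dtype=np.int64),
    )


def mc_containment_estimate(
    p: int,
    r: float,
    r_i: float,
    d: float,
    n_samples: int = 1_000_000,
    seed: int = 0,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(S_i) with its binomial standard error.

    Samples uniform points in the radius-r ball (random direction times
    radius proportional to U^(1/p), exact in any dimension) and counts the
    fraction within r_i of a query point at distance d from the center.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    hits = 0
    remaining = n_samples
    r_i_sq = r_i * r_i
    while remaining > 0:
        c = min(chunk, remaining)
        z = rng.standard_normal((c, p))
        norms = np.linalg.norm(z, axis=1)
        norms[norms == 0] = 1.0
        radii = r * rng.random(c) ** (1.0 / p)
        scale = radii / norms
        # squared distance to the query center at (d, 0, ..., 0)
        sq = radii**2 - 2.0 * d * z[:, 0] * scale + d * d
        hits += int(np.count_nonzero(sq <= r_i_sq))
        remaining -= c
    est = hits / n_samples
    se = math.sqrt(est * (1.0 - est) / n_samples)
    return est, se
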