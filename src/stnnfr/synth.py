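"""Seeded generators for the simulation study's input distributions.

Three training/query distributions: uniform on the p-ball ("spherical
uniform", the model the radius equation assumes — its worst case, with
points evenly dispersed), multivariate standard normal, and multivariate
t with 10 degrees of freedom (heavier tails, denser toward the shell),
the latter two probing robustness to violation of the spherical-uniform
assumption.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .search import ThresholdSchedule, tau_schedule

__all__ = [
    "DISTRIBUTIONS",
    "ScenarioConfig",
    "sample_spherical_uniform",
    "sample_mv_normal",
    "sample_mv_t",
    "resolve_k",
    "make_scenario",
    "write_matrix_csv",
]

DISTRIBUTIONS = ("spherical_uniform", "mv_normal", "mv_t")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: distribution, sizes, k, rings, schedule, seed.

    ``k_spec`` is either an absolute neighbor count (int >= 1) or a
    fraction of n (float in (0, 1)), resolved by round-half-up.
    """

    distribution: str
    n: int
    m: int
    p: int
    k_spec: float
    G: int = 1
    t: int = 10
    replicates: int = 1
    seed: int = 0
    df: int = 10  # degrees of freedom for mv_t

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"distribution must be one of {DISTRIBUTIONS}")
        if self.m > self.n:
            raise ValueError("query size m must not exceed training size n")
        if self.n < 1 or self.m < 1 or self.p < 1:
            raise ValueError("n, m, p must be positive")
        if self.df <= 0:
            raise ValueError("df must be positive")
        if resolve_k(self.k_spec, self.n) < 1:
            raise ValueError("k must be at least 1 after rounding")


def sample_spherical_uniform(n: int, p: int, radius: float = 1.0, seed=0) -> np.ndarray:
    """n i.i.d. points uniform on the p-ball of the given radius.

    Direction uniform on the sphere times radius proportional to U^(1/p)
    (the radial CDF of the uniform ball is (s/radius)^p).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    rad = radius * rng.random((n, 1)) ** (1.0 / p)
    return z / norms * rad


def sample_mv_normal(n: int, p: int, seed=0) -> np.ndarray:
    """n i.i.d. multivariate standard normal rows."""
    return np.random.default_rng(seed).standard_normal((n, p))


def sample_mv_t(n: int, p: int, df: int = 10, seed=0) -> np.ndarray:
    """n i.i.d. multivariate t rows with identity scale matrix.

    Normal rows scaled by sqrt(df / chi2_df); the resulting covariance is
    (df / (df - 2)) * I.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    g = rng.chisquare(df, size=(n, 1))
    return z * np.sqrt(df / g)


def resolve_k(k_spec: float, n: int) -> int:
    """Absolute k, or a fraction of n rounded half-up to a whole number."""
    if isinstance(k_spec, float) and 0 < k_spec < 1:
        return int(math.floor(k_spec * n + 0.5))
    k = int(k_spec)
    if k != k_spec:
        raise ValueError("k_spec must be an integer count or a fraction in (0, 1)")
    return k


def _sampler(config: ScenarioConfig):
    if config.distribution == "spherical_uniform":
        return lambda n, rng: sample_spherical_uniform(n, config.p, 1.0, rng)
    if config.distribution == "mv_normal":
        return lambda n, rng: sample_mv_normal(n, config.p, rng)
    return lambda n, rng: sample_mv_t(n, config.p, config.df, rng)


def make_scenario(
    config: ScenarioConfig,
) -> tuple[np.ndarray, np.ndarray, int, ThresholdSchedule]:
    """Training matrix, query matrix, resolved k, and threshold schedule."""
    rng = np.random.default_rng(config.seed)
    draw = _sampler(config)
    training = draw(config.n, rng)
    queries = draw(config.m, rng)
    k = resolve_k(config.k_spec, config.n)
    return training, queries, k, tau_schedule(k, config.n, config.t)


def write_matrix_csv(matrix: np.ndarray, path, header: bool = True) -> None:
    """Write a generated matrix to CSV (columns x1..xp) for CLI round trips."""
    X = np.asarray(matrix)
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(f"x{j + 1}" for j in range(X.shape[1])) + "\n")
        for row in X:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
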