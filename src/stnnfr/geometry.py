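"""p-dimensional hypersphere geometry.

Closed-form ball and hyperspherical-cap volumes, the volume of the
intersection of two hyperspheres, the containment probability of a query
sphere under a spherical-uniform model of the training data, and the
inverse problem: solving for the query radius that captures a target
probability mass tau.

Every probability is computed as a ratio in log space (log-Gamma for the
ball volume, the *regularized* incomplete beta for caps), so dimensions of
several hundred remain representable in double precision even though the
raw volumes overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, special

__all__ = [
    "BoundingSphere",
    "SphereIntersection",
    "ball_volume",
    "log_ball_volume",
    "cap_volume",
    "intersection_volume",
    "containment_probability",
    "solve_radius",
]

# centroid distance below _D_ZERO_GUARD * r is treated as exactly zero:
# the cap offsets c1, c2 divide by d.
_D_ZERO_GUARD = 1e-12


@dataclass(frozen=True)
class BoundingSphere:
    """A p-dimensional hypersphere: the training bound S or a query sphere S_i."""

    dimension: int
    center: tuple
    radius: float

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if len(self.center) != self.dimension:
            raise ValueError("center must have exactly `dimension` coordinates")


@dataclass(frozen=True)
class SphereIntersection:
    """Geometry of the overlap between a query sphere and the training sphere.

    ``d`` is the distance between the two centers, ``r`` the training-sphere
    radius, ``r_i`` the query-sphere radius.  ``c1``/``c2`` are the signed
    offsets of the cutting hyperplane from the two centers (NaN in the
    disjoint and containment cases, where they are never evaluated).
    ``probability`` is volume / ball_volume(p, r): the expected fraction of
    spherically-uniform training mass inside the query sphere.
    """

    dimension: int
    d: float
    r: float
    r_i: float
    c1: float
    c2: float
    volume: float
    probability: float


def log_ball_volume(p: int, radius: float) -> float:
    """Natural log of the volume of a p-ball; -inf for radius 0."""
    if p < 1:
        raise ValueError("dimension p must be a positive integer")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return -math.inf
    return (p / 2.0) * math.log(math.pi) + p * math.log(radius) - special.gammaln(p / 2.0 + 1.0)


def ball_volume(p: int, radius: float) -> float:
    """Lebesgue volume of the p-ball, pi^(p/2) radius^p / Gamma(p/2 + 1)."""
    lv = log_ball_volume(p, radius)
    return 0.0 if lv == -math.inf else math.exp(lv)


def _cap_fraction(p: int, sphere_radius: float, offset: float) -> float:
    """Fraction of a p-ball's volume on the far side of a hyperplane.

    The hyperplane sits at signed distance ``offset`` from the center;
    offset >= 0 selects the minority side.  Expressed through the
    regularized incomplete beta function I_{1-a^2/r'^2}((p+1)/2, 1/2),
    which is already a ratio and therefore safe at large p.
    """
    x = 1.0 - (offset / sphere_radius) ** 2
    x = min(max(x, 0.0), 1.0)
    half = 0.5 * special.betainc((p + 1) / 2.0, 0.5, x)
    return half if offset >= 0 else 1.0 - half


def cap_volume(p: int, sphere_radius: float, offset: float) -> float:
    """Volume of the hyperspherical cap cut at signed ``offset`` from center.

    offset >= 0 gives the minority cap; offset < 0 the complementary
    majority piece (ball volume minus the mirrored cap).
    """
    if p < 1:
        raise ValueError("dimension p must be a positive integer")
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    if abs(offset) > sphere_radius:
        raise ValueError("|offset| must not exceed sphere_radius")
    return ball_volume(p, sphere_radius) * _cap_fraction(p, sphere_radius, offset)


def _cap_offsets(r: float, r_i: float, d: float) -> tuple[float, float]:
    """Signed hyperplane offsets for the two caps of a lens intersection."""
    c1 = (d * d + r * r - r_i * r_i) / (2.0 * d)
    c2 = (d * d - r * r + r_i * r_i) / (2.0 * d)
    # clamp ~1-ulp excursions at the case boundaries
    c1 = min(max(c1, -r), r)
    c2 = min(max(c2, -r_i), r_i)
    return c1, c2


def intersection_volume(p: int, r: float, r_i: float, d: float) -> SphereIntersection:
    """Volume of the intersection of two p-balls whose centers are d apart.

    Three cases: disjoint (d >= r_i + r, volume 0); one ball inside the
    other (d <= |r_i - r|, volume of the smaller ball); otherwise a lens,
    the sum of one cap from each sphere.
    """
    if p < 1:
        raise ValueError("dimension p must be a positive integer")
    if r < 0 or r_i < 0 or d < 0:
        raise ValueError("radii and center distance must be non-negative")

    c1 = c2 = math.nan
    if d >= r_i + r:
        volume = 0.0
    elif d <= abs(r_i - r):
        volume = ball_volume(p, min(r_i, r))
    else:
        c1, c2 = _cap_offsets(r, r_i, d)
        volume = cap_volume(p, r, c1) + cap_volume(p, r_i, c2)

    prob = containment_probability(p, r, r_i, d) if r > 0 else math.nan
    return SphereIntersection(
        dimension=p, d=d, r=r, r_i=r_i, c1=c1, c2=c2, volume=volume, probability=prob
    )


def containment_probability(p: int, r: float, r_i: float, d: float) -> float:
    """P(S_i) = volume(S_i ∩ S) / volume(S): uniform training mass in the query sphere.

    ``r`` is the training-sphere radius, ``r_i`` the query-sphere radius and
    ``d`` the distance from the query point to the training centroid.
    Evaluated entirely through volume *ratios* so that p in the hundreds
    neither overflows nor underflows.
    """
    if p < 1:
        raise ValueError("dimension p must be a positive integer")
    if r <= 0:
        raise ValueError("training-sphere radius r must be positive")
    if r_i < 0 or d < 0:
        raise ValueError("r_i and d must be non-negative")

    if r_i == 0.0:
        return 0.0
    if d < _D_ZERO_GUARD * r:
        d = 0.0
    if d >= r_i + r:
        return 0.0
    if d <= abs(r_i - r):
        # smaller ball fully inside the larger; ratio min(r_i, r)^p / r^p
        if r_i >= r:
            return 1.0
        return math.exp(p * (math.log(r_i) - math.log(r)))

    c1, c2 = _cap_offsets(r, r_i, d)
    ratio = math.exp(p * (math.log(r_i) - math.log(r)))  # ball(r_i)/ball(r)
    prob = _cap_fraction(p, r, c1) + ratio * _cap_fraction(p, r_i, c2)
    return min(max(prob, 0.0), 1.0)


def solve_radius(p: int, r: float, d: float, tau: float, tol: float = 1e-10) -> float:
    """Radius r_i of the query sphere capturing probability mass ``tau``.

    Solves f(r_i | r, p, d, tau) = P(S_i) - tau = 0 by bracketed root
    finding on [0, d + r]: P is continuous and strictly increasing in r_i
    on that interval, from 0 to 1, so a bracket always exists.  tau = 1
    short-circuits to d + r, the minimal radius covering all of S.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    if r <= 0:
        raise ValueError("training-sphere radius r must be positive")
    if d < 0:
        raise ValueError("centroid distance d must be non-negative")

    if tau == 1.0:
        return d + r
    if d < _D_ZERO_GUARD * r:
        # closed form: P = (r_i/r)^p while the query ball sits inside S
        return r * tau ** (1.0 / p)

    hi = d + r

    def f(r_i: float) -> float:
        return containment_probability(p, r, r_i, d) - tau

    root = optimize.brentq(f, 0.0, hi, xtol=2e-13, rtol=8.9e-16, maxiter=200)
    # refine on the probability scale if the geometry is extremely steep
    if abs(f(root)) > tol:
        lo_b, hi_b = (root, hi) if f(root) < 0 else (0.0, root)
        for _ in range(200):
            mid = 0.5 * (lo_b + hi_b)
            fm = f(mid)
            if abs(fm) <= tol or hi_b - lo_b < 1e-16 * hi:
                root = mid
                break
            if fm < 0:
                lo_b = mid
            else:
                hi_b = mid
        else:
            raise RuntimeError("radius root refinement failed to converge")
    return root
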