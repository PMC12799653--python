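# Methods

## The problem

Brute-force k-nearest-neighbor search computes all n·m query-to-training
distances and sorts them — exact, but O(nm). `stnnfr` returns the *same*
neighbors in the *same* order while typically touching only a fraction of
the training set, by turning each query into a fixed-radius range query
against a KD-tree, with the radius chosen stochastically.

## The model

All n training points lie, by construction, inside the bounding
hypersphere S centered at the training centroid x̄ with radius
r = maxⱼ ‖xⱼ − x̄‖. Treat the training points as if drawn from the
spherical uniform distribution on S (density 1/volume(S)). For a query at
centroid distance d with search sphere S_i of radius r_i, the expected
fraction of training mass captured is the containment probability

P(S_i) = volume(S_i ∩ S) / volume(S).

The intersection volume has three cases: zero when d ≥ r_i + r; the
smaller ball's volume when d ≤ |r_i − r|; otherwise the sum of two
hyperspherical caps cut at signed offsets c1 = (d² + r² − r_i²)/(2d) and
c2 = (d² − r² + r_i²)/(2d) from the respective centers. A cap at offset
a ≥ 0 on a ball of radius r′ has volume
(π^(p/2)/2)·(r′^p/Γ(p/2+1))·I_{1−a²/r′²}((p+1)/2, 1/2), with I the
regularized incomplete beta function; a < 0 gives the complementary
majority piece.

Given a target mass τ ∈ (0,1], the query radius solves
f(r_i | r, p, d, τ) = P(S_i) − τ = 0. P is continuous and strictly
increasing in r_i from 0 (at r_i = 0) to 1 (at r_i = d + r), so a
bracketed root always exists.

## The search

Thresholds form an ascending schedule T = (τ⁽¹⁾, …, τ⁽ᵗ⁾), t = 10 values
evenly spaced from k/n to 1. Starting at τ⁽¹⁾ = k/n — the mass that
*expects* to contain exactly k points — each query submits a KD-tree
range query at the solved radius; if fewer than k candidates fall inside,
τ escalates to the next schedule value. The final threshold 1 solves to
radius d + r, which by the triangle inequality covers all of S, so
termination with k′ ≥ k candidates is guaranteed within t iterations.
The k candidates smallest by (distance, training-row index) are returned.

Exactness does not depend on the distributional assumption: whenever at
least k points lie within the search radius, the k-th smallest overall
distance is at most that radius, so every true neighbor is in the
candidate set. The assumption only controls how many iterations the
sweep needs — one, on average, in the simulations below.

### Ring groups

The radius equation depends on the query only through d, so queries are
binned into G concentric rings of equal spherical-uniform mass with
boundaries δ_g = r·(g/G)^(1/p) (closed on the right; δ_G = r exactly).
All queries in ring g share the radius solved at d = δ_g — conservative,
since P is non-increasing in d — so at most G×t equations are solved per
run, cached per (ring, τ). G never changes the output, only the work:
a larger shared radius can only enlarge the candidate set.

Queries outside S fall into an overflow group G+1, which the ring
construction does not cover; their radius is solved per query at their
actual centroid distance. Such queries are rare under the model and
always terminate (the τ = 1 radius still covers S).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| k | neighbors returned | required | problem-defined |
| G | ring-group count | 1 | fastest in the simulations; no effect on results |
| t | schedule length | 10 | sweep bound; first threshold k/n already suffices on average |
| τ schedule | thresholds | k/n → 1, evenly spaced | starts at the mass expecting exactly k points; must end at 1 for the covering guarantee |

## Numerical choices

- All volume ratios are computed in log space (log-Gamma, and the
  *regularized* incomplete beta, itself a ratio), so p in the hundreds
  neither overflows nor underflows; raw volumes as printed formulas
  overflow double precision near p ≈ 340.
- Root finding: Brent's method bracketed on [0, d + r], followed by a
  bisection refinement if the forward-evaluated probability misses τ by
  more than 1e−10 (relevant only where P is extremely steep in r_i, i.e.
  very large p).
- d = 0 (and d < 1e−12·r) short-circuits to the closed form
  r·τ^(1/p): the cap offsets divide by d. τ = 1 short-circuits to d + r
  exactly.
- Case boundaries (d = r_i + r, d = |r_i − r|) resolve by the first
  matching ≥/≤ comparison, and near-boundary cap offsets are clamped to
  [−r, r] against 1-ulp excursions.
- Tie-breaking is ascending (distance, training-row index), applied
  identically in the sweep search and the brute-force comparator; both
  compute distances with the same row-wise norm expression so orderings
  are bit-stable. A degenerate training set (all rows identical, r = 0)
  bypasses the geometry and returns the first k rows.
- Row indices are 0-based in the API, 1-based in the TSV output (stated
  in its header comment).

## Synthetic data

Three generators emulate the simulation inputs: uniform on the unit
p-ball (direction × radius ∝ U^(1/p); the model's own — worst-case —
assumption with points evenly dispersed), multivariate standard normal,
and multivariate t with df = 10 and identity *scale* matrix (covariance
(df/(df−2))·I; the identity is read as the scale parameter, the standard
sampler convention), probing robustness when the uniform assumption is
violated. Fractional k specifications (e.g. 0.16n) round half-up. All
generators are pure functions of (parameters, seed).

What the generators do not emulate: correlated features, cluster
structure, or group-specific covariances of real datasets. Passing tests
therefore demonstrate exactness and the iteration behavior under these
three idealized dispersions — exactness itself holds for any data (it is
distribution-free, see above), but single-iteration convergence on real,
clustered data is not implied.

## Problem sizes used

The shipped checks run a reduced grid — distributions × n ∈ {100, 1000,
10000} × m ∈ {50, 100} × p ∈ {5, 20, 50} × k ∈ {1, 0.16n} × G ∈ {1, 5},
5 replicates — chosen to complete in minutes on a single CPU; the bench
CLI accepts arbitrary YAML grids for larger studies. The mean-iteration
check uses n = 1000, m = 100, p = 20, k = 160, G = 1 over 25 replicates;
the coverage check uses 10⁶ Monte-Carlo samples.

## Known limitations

- Euclidean distance only: the containment-probability argument is
  volume-based and metric-specific.
- KD-tree range queries degenerate toward linear scans as p grows; the
  win over brute force comes from scanning only the candidate ball and
  from solving G×t equations instead of m, not from tree asymptotics at
  high p.
- Wall-clock and memory figures from the benchmark harness are
  host-dependent and informational only; correctness (exact agreement
  with brute force) is the only gate.
- Queries far outside the bounding sphere may need more than one sweep
  iteration (the early thresholds' lens geometry captures little mass);
  the schedule bound t still holds.
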