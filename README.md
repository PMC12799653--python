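# stnnfr

Exact k-nearest-neighbor search via **st**ochastic fixed-**r**adius
queries (STNNfr) — the same neighbors as a brute-force scan, in the same
order, at a fraction of the distance computations.

## Who this is for

Anyone running kNN search (classification, regression, imputation,
matching) on large training sets where the O(nm) brute-force scan is the
bottleneck: health-records cohorts, national registries, high-dimensional
feature matrices. The method is exact — there is no accuracy trade-off —
so it is a drop-in replacement for a linear scan.

## The idea

All n training points lie inside the bounding hypersphere S centered at
the training centroid x̄ with radius r = maxⱼ‖xⱼ − x̄‖, so no neighbor can
be outside S. For a query at centroid distance d, model the training
points as spherically uniform on S; then a query sphere of radius r_i
captures expected mass

P(S_i) = volume(S_i ∩ S) / volume(S),

computable in closed form from hyperspherical-cap volumes (regularized
incomplete beta function). Solving P(S_i) = τ with τ = k/n gives a radius
expected to contain exactly k training points; a KD-tree fixed-radius
query retrieves the candidates, and if fewer than k arrive, τ escalates
through an evenly spaced 10-value schedule ending at 1, whose radius
d + r provably covers all of S. Whenever ≥ k candidates are inside the
radius, the true k nearest are among them, so the output is exact
regardless of the actual data distribution. Queries are binned into G
concentric rings of equal model mass that share solved radii, so at most
G×t radius equations are solved per run.

## Worked example

```python
import numpy as np
from stnnfr import (fit_index, knn_search, tau_schedule,
                    brute_force_knn, sample_spherical_uniform)

train = sample_spherical_uniform(1000, 20, 1.0, seed=1)
queries = sample_spherical_uniform(5, 20, 1.0, seed=2)

index = fit_index(train)                 # centroid, bounding radius, KD-tree
print("r =", round(index.bounding_radius, 4))
sched = tau_schedule(5, 1000, 10)        # k/n = 0.005 up to 1.0
res = knn_search(index, queries, k=5, G=1, schedule=sched)
print("first query neighbors:", res.indices[0], res.distances[0].round(4))
print("iterations:", res.iterations, " candidates k':", res.candidates_found)
print("identical to brute force:",
      np.array_equal(res.indices, brute_force_knn(train, queries, 5).indices))
```

prints

```
r = 1.012
first query neighbors: [326 404 952 157 954] [0.714  0.8626 0.8687 0.8858 0.8934]
iterations: [1 1 1 1 1]  candidates k': [11 11  9  6 16]
identical to brute force: True
```

Every query converged on the first threshold: the τ = k/n radius
captured between 6 and 16 candidates (k′), of which the 5 closest were
kept — against 1000 distance computations per query for the brute-force
scan. The indices are 0-based here; the TSV output of the CLI is 1-based.

## Command line

```sh
stnnfr query --train train.csv --query query.csv -k 15 -G 1 --oracle --out nn.tsv
stnnfr bench --config grid.yaml --out records.csv
stnnfr generate --dist spherical_uniform -n 1000 -p 20 --seed 1 --out train.csv
```

`query` reads CSV/TSV matrices (header auto-detected), writes a TSV of
(query_id, rank, train_index, distance), and with `--oracle` verifies
exact agreement against the brute-force comparator before writing.
`bench` expands a YAML scenario grid (list values expand Cartesian over
distribution, n, m, p, k_spec, G, t), runs both methods on every
replicate with exact agreement as a hard gate, and writes per-replicate
records plus a summary; timing and memory columns are informational.

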