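"""Training index, ring grouping, threshold sweep, and exact-kNN equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stnnfr.geometry import containment_probability, solve_radius
from stnnfr.oracle import brute_force_knn
from stnnfr.search import (
    RingPartition,
    ThresholdSchedule,
    assign_groups,
    fit_index,
    fixed_radius_candidates,
    knn_search,
    ring_radii,
    tau_schedule,
    top_k_select,
)
from stnnfr.synth import ScenarioConfig, make_scenario


# ---------------------------------------------------------------------------
# training index


def test_fit_index_square_symmetry():
    index = fit_index([[0, 0], [2, 0], [0, 2], [2, 2]])
    assert index.centroid == pytest.approx([1.0, 1.0])
    assert index.bounding_radius == pytest.approx(math.sqrt(2))


def test_fit_index_single_row_degenerate():
    index = fit_index([[3.0, -1.0, 2.0]])
    assert index.centroid == pytest.approx([3.0, -1.0, 2.0])
    assert index.bounding_radius == 0.0


def test_fit_index_radius_matches_direct_recomputation(rng):
    X = rng.standard_normal((200, 10))
    index = fit_index(X)
    direct = np.linalg.norm(X - X.mean(axis=0), axis=1).max()
    assert index.bounding_radius == direct
    assert (index.centroid_distances <= index.bounding_radius).all()


@pytest.mark.parametrize(
    "bad",
    [np.empty((0, 3)), [[1.0, np.nan], [0.0, 1.0]], [[1.0, np.inf], [0.0, 1.0]]],
)
def test_fit_index_rejects_invalid_input(bad):
    with pytest.raises(ValueError):
        fit_index(bad)


# ---------------------------------------------------------------------------
# ring radii and group assignment


def test_ring_radii_g3_p2_closed_form():
    delta = ring_radii(1.0, 2, 3)
    assert delta == pytest.approx([math.sqrt(1 / 3), math.sqrt(2 / 3), 1.0])


def test_ring_radii_single_group_is_bounding_radius():
    assert ring_radii(2.5, 7, 1) == pytest.approx([2.5])


def test_ring_radii_collapse_toward_shell_at_high_dimension():
    delta = ring_radii(1.0, 250, 10)
    assert delta[0] == pytest.approx(0.1 ** (1 / 250))
    assert delta[0] > 0.99


def test_ring_radii_rejects_bad_group_count():
    with pytest.raises(ValueError):
        ring_radii(1.0, 2, 0)


def test_assign_groups_boundaries_closed_on_right():
    # symmetric cross: centroid (0,0), bounding radius 1
    index = fit_index([[1, 0], [-1, 0], [0, 1], [0, -1]])
    partition = RingPartition(index.bounding_radius, 2, 3)
    delta = partition.boundary_radii
    queries = np.array(
        [
            [0.0, 0.0],  # centroid → group 1
            [delta[1], 0.0],  # exactly delta_2 → group 2 (closed right)
            [0.5 * (delta[1] + delta[2]), 0.0],  # inside ring 3
            [2.0, 0.0],  # outside S → group G+1
        ]
    )
    assignment = assign_groups(index, queries, partition)
    assert assignment.group_ids.tolist() == [1, 2, 3, 4]


def test_assign_groups_rejects_dimension_mismatch():
    index = fit_index([[1, 0], [-1, 0]])
    partition = RingPartition(index.bounding_radius, 2, 2)
    with pytest.raises(ValueError):
        assign_groups(index, [[0.0, 0.0, 0.0]], partition)


# ---------------------------------------------------------------------------
# threshold schedule


def test_tau_schedule_evenly_spaced_from_k_over_n():
    sched = tau_schedule(10, 100, 10)
    assert np.allclose(sched.values, np.arange(1, 11) / 10)
    assert sched.values[-1] == 1.0


def test_tau_schedule_degenerate_k_equals_n():
    assert tau_schedule(5, 5, 10).values == (1.0,)


def test_tau_schedule_small_k_step():
    sched = tau_schedule(1, 1000, 10)
    assert sched.values[0] == pytest.approx(0.001)
    assert sched.values[1] - sched.values[0] == pytest.approx((1 - 0.001) / 9)


def test_tau_schedule_rejects_k_above_n():
    with pytest.raises(ValueError):
        tau_schedule(11, 10, 10)


@pytest.mark.parametrize(
    "values",
    [(0.5, 0.4, 1.0), (0.2, 0.9), (0.0, 1.0), ()],
)
def test_threshold_schedule_invariants(values):
    with pytest.raises(ValueError):
        ThresholdSchedule(values=values)


# ---------------------------------------------------------------------------
# ring-group radii


def test_group_radius_tau_one_is_twice_bounding_radius():
    partition = RingPartition(1.5, 4, 3)
    assert partition.group_radius(3, 1.0) == pytest.approx(3.0)


def test_group_radius_forward_evaluation_2d():
    partition = RingPartition(1.0, 2, 1)
    r_sol = partition.group_radius(1, 0.25)
    assert containment_probability(2, 1.0, r_sol, 1.0) == pytest.approx(0.25, abs=1e-9)


def test_group_radius_conservative_for_interior_queries():
    """Solving at the ring's outer edge dominates any interior query's need."""
    partition = RingPartition(1.0, 5, 2)
    group_r = partition.group_radius(1, 0.3)
    interior_r = solve_radius(5, 1.0, 0.2, 0.3)
    assert interior_r <= group_r
    # probability at the interior query's own distance is >= tau
    assert containment_probability(5, 1.0, group_r, 0.2) >= 0.3


def test_group_radius_cache_solves_each_equation_once():
    partition = RingPartition(1.0, 10, 4)
    sched = tau_schedule(5, 100, 10)
    for _ in range(3):  # repeated sweeps hit the cache
        for g in range(1, 5):
            for tau in sched.values:
                partition.group_radius(g, tau)
    assert partition.equations_solved == 4 * 10


def test_group_radius_rejects_overflow_group():
    partition = RingPartition(1.0, 3, 2)
    with pytest.raises(ValueError):
        partition.group_radius(3, 0.5)


# ---------------------------------------------------------------------------
# fixed-radius candidates


def test_fixed_radius_candidates_matches_linear_scan(rng):
    X = rng.standard_normal((300, 6))
    index = fit_index(X)
    q = rng.standard_normal(6)
    for radius in (0.5, 1.5, 3.0):
        idx, dist = fixed_radius_candidates(index, q, radius)
        direct = np.linalg.norm(X - q, axis=1)
        expected = np.nonzero(direct <= radius)[0]
        assert np.array_equal(idx, expected)
        assert np.array_equal(dist, direct[expected])


def test_fixed_radius_candidates_covering_radius_returns_all(rng):
    X = rng.standard_normal((50, 4))
    index = fit_index(X)
    q = np.zeros(4)
    d = float(np.linalg.norm(q - index.centroid))
    idx, _ = fixed_radius_candidates(index, q, d + index.bounding_radius + 1e-9)
    assert idx.size == 50


def test_fixed_radius_candidates_empty_below_smallest_distance():
    index = fit_index([[1.0, 0.0], [-1.0, 0.0]])
    idx, dist = fixed_radius_candidates(index, [0.0, 0.0], 0.5)
    assert idx.size == 0 and dist.size == 0


# ---------------------------------------------------------------------------
# top-k selection


def test_top_k_select_orders_by_distance():
    idx, dist = top_k_select([10, 11, 12], [3.0, 1.0, 2.0], 2)
    assert idx.tolist() == [11, 12]
    assert dist.tolist() == [1.0, 2.0]


def test_top_k_select_breaks_ties_by_training_index():
    idx, _ = top_k_select([7, 3, 5], [1.0, 1.0, 1.0], 2)
    assert idx.tolist() == [3, 5]


def test_top_k_select_matches_full_sort_prefix(rng):
    cand = rng.permutation(100)
    dist = rng.random(100).round(1)  # deliberate ties
    idx, d = top_k_select(cand, dist, 10)
    order = np.lexsort((cand, dist))
    assert np.array_equal(idx, cand[order[:10]])
    assert np.array_equal(d, dist[order[:10]])


def test_top_k_select_rejects_too_few_candidates():
    with pytest.raises(ValueError):
        top_k_select([1, 2], [0.1, 0.2], 3)


# ---------------------------------------------------------------------------
# the full search


@pytest.mark.parametrize("dist", ["spherical_uniform", "mv_normal", "mv_t"])
@pytest.mark.parametrize("G", [1, 3])
def test_knn_search_equals_brute_force(dist, G):
    tr, q, k, sched = make_scenario(
        ScenarioConfig(dist, n=400, m=30, p=8, k_spec=7, seed=99)
    )
    index = fit_index(tr)
    res = knn_search(index, q, k, G=G, schedule=sched)
    bf = brute_force_knn(tr, q, k)
    assert np.array_equal(res.indices, bf.indices)
    assert np.array_equal(res.distances, bf.distances)
    assert (res.candidates_found >= k).all()
    assert (res.iterations >= 1).all() and (res.iterations <= len(sched)).all()


def test_knn_search_spherical_uniform_headline_scenario():
    """The headline property: identical neighbors, identical order."""
    tr, q, k, sched = make_scenario(
        ScenarioConfig("spherical_uniform", n=1000, m=50, p=20, k_spec=5, seed=31)
    )
    index = fit_index(tr)
    res = knn_search(index, q, k, schedule=sched)
    bf = brute_force_knn(tr, q, k)
    assert np.array_equal(res.indices, bf.indices)
    assert np.array_equal(res.distances, bf.distances)


def test_knn_search_k_equals_n_returns_everything_in_order(rng):
    X = rng.standard_normal((40, 3))
    q = rng.standard_normal((5, 3))
    index = fit_index(X)
    res = knn_search(index, q, 40)
    bf = brute_force_knn(X, q, 40)
    assert np.array_equal(res.indices, bf.indices)
    assert (np.diff(res.distances, axis=1) >= 0).all()


def test_knn_search_query_coincident_with_training_point(rng):
    X = rng.standard_normal((60, 4))
    res = knn_search(fit_index(X), X[17], 3)
    assert res.indices[0, 0] == 17
    assert res.distances[0, 0] == 0.0


def test_knn_search_degenerate_identical_training_rows():
    X = np.ones((10, 3))
    res = knn_search(fit_index(X), [[2.0, 1.0, 1.0]], 4)
    assert res.indices[0].tolist() == [0, 1, 2, 3]
    assert res.distances[0] == pytest.approx([1.0] * 4)


def test_knn_search_tied_distances_prefer_lower_training_index():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0], [3.0, 3.0]])
    res = knn_search(fit_index(X), [[0.0, 0.0]], 3)
    assert res.indices[0].tolist() == [0, 1, 2]
    bf = brute_force_knn(X, [[0.0, 0.0]], 3)
    assert np.array_equal(res.indices, bf.indices)


def test_knn_search_far_outside_query_terminates_within_schedule(rng):
    """Overflow-group queries (outside S) still finish, exactly, within t."""
    X = rng.standard_normal((200, 5))
    index = fit_index(X)
    far = index.centroid + 100.0 * index.bounding_radius * np.r_[1.0, np.zeros(4)]
    sched = tau_schedule(5, 200, 10)
    res = knn_search(index, [far], 5, schedule=sched)
    bf = brute_force_knn(X, [far], 5)
    assert np.array_equal(res.indices, bf.indices)
    assert res.iterations[0] <= len(sched)


def test_knn_search_rejects_k_above_n(rng):
    X = rng.standard_normal((10, 2))
    with pytest.raises(ValueError):
        knn_search(fit_index(X), [[0.0, 0.0]], 11)


def test_knn_search_g_invariance_identical_outputs():
    tr, q, k, sched = make_scenario(
        ScenarioConfig("mv_normal", n=500, m=40, p=10, k_spec=0.16, seed=77)
    )
    index = fit_index(tr)
    base = knn_search(index, q, k, G=1, schedule=sched)
    for G in (2, 5, 10):
        res = knn_search(index, q, k, G=G, schedule=sched)
        assert np.array_equal(res.indices, base.indices)
        assert np.array_equal(res.distances, base.distances)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**20),
    n=st.integers(5, 120),
    p=st.integers(1, 10),
    k=st.integers(1, 5),
    G=st.integers(1, 4),
)
def test_knn_search_property_exactness(seed, n, p, k, G):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Q = rng.standard_normal((4, p))
    k = min(k, n)
    res = knn_search(fit_index(X), Q, k, G=G)
    bf = brute_force_knn(X, Q, k)
    assert np.array_equal(res.indices, bf.indices)
    assert np.array_equal(res.distances, bf.distances)
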