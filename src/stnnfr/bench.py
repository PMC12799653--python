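"""Benchmark harness: run scenarios, gate on exact agreement, record metrics.

Correctness is a gate, not a metric: any disagreement between the
fixed-radius search and the brute-force comparator aborts the run with a
diagnostic dump.  Timing and memory figures are informational only —
they depend on the host and are never part of automated acceptance.
"""

from __future__ import annotations

import itertools
import time
import tracemalloc
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .oracle import brute_force_knn
from .search import fit_index, knn_search
from .synth import ScenarioConfig, make_scenario

__all__ = ["BenchmarkRecord", "AgreementError", "run_scenario", "expand_grid", "summarize"]


class AgreementError(RuntimeError):
    """The two search methods disagreed — a hard failure, never a metric."""


@dataclass(frozen=True)
class BenchmarkRecord:
    distribution: str
    n: int
    m: int
    p: int
    k: int
    G: int
    t: int
    replicate: int
    seed: int
    agreement: bool
    mean_iterations: float
    max_iterations: int
    elapsed_stnnfr: float
    elapsed_brute: float
    mem_delta_stnnfr: int
    mem_delta_brute: int


def _timed(fn, measure_memory: bool):
    if measure_memory:
        tracemalloc.start()
        t0 = time.perf_counter()
        out = fn()
        elapsed = time.perf_counter() - t0
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        return out, elapsed, peak
    t0 = time.perf_counter()
    out = fn()
    return out, time.perf_counter() - t0, 0


def _diagnose(i, stnnfr, brute, config, k):
    bad = np.nonzero(
        (stnnfr.indices[i] != brute.indices[i]) | (stnnfr.distances[i] != brute.distances[i])
    )[0]
    return (
        f"neighbor disagreement for query {i} in scenario {config.distribution} "
        f"(n={config.n}, m={config.m}, p={config.p}, k={k}, G={config.G}, "
        f"seed={config.seed}): ranks {bad.tolist()}; "
        f"stnnfr indices {stnnfr.indices[i].tolist()} "
        f"distances {stnnfr.distances[i].tolist()} "
        f"(k'={int(stnnfr.candidates_found[i])}, "
        f"iterations={int(stnnfr.iterations[i])}); "
        f"brute indices {brute.indices[i].tolist()} "
        f"distances {brute.distances[i].tolist()}"
    )


def run_scenario(config: ScenarioConfig, measure_memory: bool = True) -> list[BenchmarkRecord]:
    """Run every replicate of a scenario, verifying exact agreement.

    Per-replicate seeds are spawned deterministically from the base seed.
    """
    records: list[BenchmarkRecord] = []
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rep_config = replace(config, seed=rep_seed, replicates=1)
        training, queries, k, schedule = make_scenario(rep_config)

        def _run_stnnfr():
            index = fit_index(training)
            return knn_search(index, queries, k, G=config.G, schedule=schedule)

        stnnfr_res, t_stnnfr, mem_stnnfr = _timed(_run_stnnfr, measure_memory)
        brute_res, t_brute, mem_brute = _timed(
            lambda: brute_force_knn(training, queries, k), measure_memory
        )

        agreement = bool(
            np.array_equal(stnnfr_res.indices, brute_res.indices)
            and np.array_equal(stnnfr_res.distances, brute_res.distances)
        )
        if not agreement:
            first_bad = int(
                np.nonzero((stnnfr_res.indices != brute_res.indices).any(axis=1))[0][0]
            )
            raise AgreementError(_diagnose(first_bad, stnnfr_res, brute_res, rep_config, k))

        records.append(
            BenchmarkRecord(
                distribution=config.distribution,
                n=config.n,
                m=config.m,
                p=config.p,
                k=k,
                G=config.G,
                t=config.t,
                replicate=rep,
                seed=rep_seed,
                agreement=agreement,
                mean_iterations=float(stnnfr_res.iterations.mean()),
                max_iterations=int(stnnfr_res.iterations.max()),
                elapsed_stnnfr=t_stnnfr,
                elapsed_brute=t_brute,
                mem_delta_stnnfr=mem_stnnfr,
                mem_delta_brute=mem_brute,
            )
        )
    return records


_GRID_KEYS = ("distribution", "n", "m", "p", "k_spec", "G", "t")


def expand_grid(config: dict) -> list[ScenarioConfig]:
    """Expand a flat config mapping into scenarios (list values → Cartesian).

    Recognized keys: distribution, n, m, p, k_spec, G, t (scalar or list),
    plus scalar replicates, seed, df.  Unknown keys are an error, named.
    """
    known = set(_GRID_KEYS) | {"replicates", "seed", "df"}
    for key in config:
        if key not in known:
            raise ValueError(f"unknown config key: {key!r}")
    for key in ("distribution", "n", "m", "p", "k_spec"):
        if key not in config:
            raise ValueError(f"missing config key: {key!r}")
    axes = []
    for key in _GRID_KEYS:
        val = config.get(key, {"G": 1, "t": 10}.get(key))
        axes.append(val if isinstance(val, (list, tuple)) else [val])
    fixed = {key: config.get(key, 0 if key == "seed" else (10 if key == "df" else 1))
             for key in ("replicates", "seed", "df")}
    scenarios = []
    for combo in itertools.product(*axes):
        params = dict(zip(_GRID_KEYS, combo))
        if params["m"] > params["n"]:
            continue  # the simulation design constrains m <= n
        try:
            scenarios.append(ScenarioConfig(**params, **fixed))
        except ValueError as exc:
            raise ValueError(f"invalid scenario {params}: {exc}") from exc
    return scenarios


def records_frame(records: list[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([{f.name: getattr(rec, f.name) for f in fields(rec)} for rec in records])


def summarize(records: list[BenchmarkRecord]) -> pd.DataFrame:
    """Per-scenario means over replicates of the informational metrics."""
    df = records_frame(records)
    keys = ["distribution", "n", "m", "p", "k", "G", "t"]
    return (
        df.groupby(keys, as_index=False)
        .agg(
            replicates=("replicate", "count"),
            agreement=("agreement", "all"),
            mean_iterations=("mean_iterations", "mean"),
            max_iterations=("max_iterations", "max"),
            elapsed_stnnfr=("elapsed_stnnfr", "mean"),
            elapsed_brute=("elapsed_brute", "mean"),
            mem_delta_stnnfr=("mem_delta_stnnfr", "mean"),
            mem_delta_brute=("mem_delta_brute", "mean"),
        )
    )
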