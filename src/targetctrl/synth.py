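"""Synthetic networks, target-selection protocols and repeated-run evaluation.

Generators emulate the two topology families used in the evaluation
protocol: Erdős–Rényi digraphs (each ordered pair carries an edge
independently) and preferential-attachment digraphs with a heavy in-degree
tail.  Targets are drawn either uniformly at random or as a local
breadth-first ball; algorithm runs are repeated with derived seeds (seed +
repeat index) and summarized by the driver-to-target ratio |D|/|T| and a
consensus driver set — the vertices recurring in at least a stated fraction
of runs (default 0.9, i.e. nine of ten).

The BFS-ball notion of "local" selection is this package's own construction;
see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean, pstdev

import numpy as np

from .gtca import GTCAConfig, run_gtca
from .network import DirectedNetwork, VertexSelector, as_selector
from .rank import RankEngineConfig
from .structural import structural_target_control, two_step

__all__ = [
    "EvalSummary",
    "gen_erdos_renyi",
    "gen_scale_free",
    "select_targets_random",
    "select_targets_local",
    "consensus_drivers",
    "evaluate",
]

DEFAULT_REPEATS = 20
DEFAULT_CONSENSUS_THRESHOLD = 0.9


def _labels(n: int) -> tuple[str, ...]:
    return tuple(str(i) for i in range(1, n + 1))


def gen_erdos_renyi(n: int, edge_prob: float, seed: int | None = None) -> DirectedNetwork:
    """Erdős–Rényi digraph: each ordered pair (u != v) is an edge with
    probability ``edge_prob``; unit weights; bit-reproducible under a seed."""
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    draws = rng.random((n, n))
    edges = tuple(
        (labels[i], labels[j], 1)
        for i in range(n) for j in range(n)
        if i != j and draws[i, j] < edge_prob
    )
    return DirectedNetwork(labels, edges)


def gen_scale_free(n: int, attachment: int = 2, seed: int | None = None) -> DirectedNetwork:
    """Preferential-attachment digraph with a heavy in-degree tail.

    Starts from a 2-cycle seed graph; each new vertex sends ``attachment``
    edges to distinct existing vertices chosen with probability proportional
    to in-degree + 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if attachment < 1:
        raise ValueError("attachment must be >= 1")
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    edges: list[tuple[str, str, int]] = [(labels[0], labels[1], 1), (labels[1], labels[0], 1)]
    in_deg = [1, 1]
    for v in range(2, n):
        k = min(attachment, v)
        weights = np.array(in_deg[:v], dtype=float) + 1.0
        targets = rng.choice(v, size=k, replace=False, p=weights / weights.sum())
        for t in targets:
            edges.append((labels[v], labels[int(t)], 1))
            in_deg[int(t)] += 1
        in_deg.append(0)
    return DirectedNetwork(labels, tuple(edges))


def select_targets_random(net: DirectedNetwork, fraction: float,
                          seed: int | None = None) -> VertexSelector:
    """Uniform sample without replacement of ceil(fraction * n) vertices,
    returned in network order."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * net.n)
    rng = np.random.default_rng(seed)
    picked = rng.choice(net.n, size=k, replace=False)
    chosen = set(int(i) for i in picked)
    return VertexSelector(tuple(v for i, v in enumerate(net.vertices) if i in chosen),
                          "target")


def select_targets_local(net: DirectedNetwork, fraction: float,
                         seed: int | None = None) -> VertexSelector:
    """Breadth-first ball on the underlying undirected graph.

    Grows from a seeded start vertex until ceil(fraction * n) vertices are
    collected; when a component is exhausted before the quota is met, a new
    random unvisited start is drawn.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    quota = math.ceil(fraction * net.n)
    rng = np.random.default_rng(seed)
    neighbors: dict[str, list[str]] = {v: [] for v in net.vertices}
    for u, v, _ in net.edges:
        if v not in neighbors[u]:
            neighbors[u].append(v)
        if u != v and u not in neighbors[v]:
            neighbors[v].append(u)

    collected: list[str] = []
    visited: set[str] = set()
    while len(collected) < quota:
        candidates = [v for v in net.vertices if v not in visited]
        start = candidates[int(rng.integers(len(candidates)))]
        queue = [start]
        visited.add(start)
        while queue and len(collected) < quota:
            v = queue.pop(0)
            collected.append(v)
            for w in neighbors[v]:
                if w not in visited:
                    visited.add(w)
                    queue.append(w)
    return VertexSelector(tuple(collected), "target")


def consensus_drivers(runs, threshold: float = DEFAULT_CONSENSUS_THRESHOLD) -> VertexSelector:
    """Vertices appearing in at least ``threshold`` of the runs.

    With the default 0.9 and ten runs this is the nine-of-ten consensus rule;
    the result shrinks monotonically as the threshold rises.
    """
    runs = [tuple(r) for r in runs]
    if not runs:
        raise ValueError("need at least one run")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    counts: dict[str, int] = {}
    order: list[str] = []
    for r in runs:
        for v in set(r):
            if v not in counts:
                counts[v] = 0
                order.append(v)
            counts[v] += 1
    keep = tuple(v for v in order if counts[v] / len(runs) >= threshold)
    return VertexSelector(keep, "driver")


@dataclass
class EvalSummary:
    """Repeated-run evaluation of one algorithm on one network."""

    algorithm: str
    driver_sets: tuple[tuple[str, ...], ...]
    ratios: tuple[float, ...]          # |D| / |T| per run
    mean_ratio: float
    sd_ratio: float
    consensus: VertexSelector
    seeds: tuple[int, ...]
    target_count: int

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "driver_sets": [list(s) for s in self.driver_sets],
            "ratios": list(self.ratios),
            "mean_ratio": self.mean_ratio,
            "sd_ratio": self.sd_ratio,
            "consensus": list(self.consensus.labels),
            "seeds": list(self.seeds),
            "target_count": self.target_count,
        }


def evaluate(net: DirectedNetwork, targets, algorithm: str = "gtca",
             repeats: int = DEFAULT_REPEATS, seed: int = 0,
             threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
             engine: RankEngineConfig | None = None) -> EvalSummary:
    """Run an algorithm ``repeats`` times with derived seeds (seed + index).

    ``algorithm`` is ``"gtca"``, ``"structural"`` or ``"twostep"`` (for the
    two-step composition the reported driver sets are the structural stage's
    output).  Reports per-run |D|/|T| ratios, their mean and population SD,
    and the consensus driver set at the given threshold.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    T = as_selector(targets, "target")
    if len(T) == 0:
        raise ValueError("target set must be nonempty")
    seeds = tuple(seed + i for i in range(repeats))
    sets: list[tuple[str, ...]] = []
    for s in seeds:
        if algorithm == "gtca":
            cfg = GTCAConfig(seed=s, engine=engine or RankEngineConfig())
            sets.append(run_gtca(net, T, cfg).drivers)
        elif algorithm == "structural":
            sets.append(structural_target_control(net, T, seed=s))
        elif algorithm == "twostep":
            cfg = GTCAConfig(seed=s, engine=engine or RankEngineConfig())
            sets.append(two_step(net, T, cfg).structural_drivers)
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
    ratios = tuple(len(s) / len(T) for s in sets)
    return EvalSummary(
        algorithm=algorithm,
        driver_sets=tuple(sets),
        ratios=ratios,
        mean_ratio=mean(ratios),
        sd_ratio=pstdev(ratios) if repeats > 1 else 0.0,
        consensus=consensus_drivers(sets, threshold),
        seeds=seeds,
        target_count=len(T),
    )
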