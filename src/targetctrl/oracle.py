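"""Ground-truth references: exhaustive minimum-driver search and a
Monte-Carlo generic-rank check.

Target controllability is NP-hard, so the exhaustive search is only viable
on small instances; it is the package's oracle for validating the greedy
heuristics.  The generic-rank check probes *structural* controllability
numerically: the rank of a patterned matrix attains its generic maximum for
almost every weight assignment, so redrawing weights from a continuous
distribution and checking Kalman's condition per draw estimates whether a
driver set controls the targets generically even when the unit-weight
(exact) rank falls short.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .network import DirectedNetwork, as_selector, state_matrix
from .rank import RankEngineConfig, control_matrix_rank

__all__ = ["OracleReport", "brute_force_min_drivers", "generic_rank_check"]


@dataclass
class OracleReport:
    """All minimum driver sets found by exhaustive enumeration."""

    min_size: int
    min_sets: tuple[tuple[str, ...], ...]
    subsets_examined: int
    engine: RankEngineConfig


def brute_force_min_drivers(net: DirectedNetwork, targets,
                            engine: RankEngineConfig | None = None,
                            max_n: int = 12,
                            candidate_pool=None) -> OracleReport:
    """Enumerate vertex subsets by size until a full-rank driver set appears.

    Subsets are visited in lexicographic order of the vertex ordering; every
    subset of the first feasible size is reported.  ``candidate_pool``
    optionally restricts enumeration to a vertex subset — a heuristic prune
    that can miss true minima; leave it ``None`` for oracle integrity.

    Refuses networks with more than ``max_n`` vertices (combinatorial
    blow-up).
    """
    if net.n > max_n:
        raise ValueError(f"brute force refused: n={net.n} exceeds max_n={max_n}")
    T = as_selector(targets, "target")
    if len(T) == 0:
        raise ValueError("target set must be nonempty")
    engine = engine or RankEngineConfig()
    A = state_matrix(net)
    pool = tuple(candidate_pool) if candidate_pool is not None else net.vertices
    m = len(T)
    examined = 0
    for size in range(1, len(pool) + 1):
        hits: list[tuple[str, ...]] = []
        for subset in combinations(pool, size):
            examined += 1
            if control_matrix_rank(A, subset, T, engine) == m:
                hits.append(subset)
        if hits:
            return OracleReport(size, tuple(hits), examined, engine)
    raise RuntimeError("no controlling subset found (unreachable: D = V always works)")


def generic_rank_check(net: DirectedNetwork, drivers, targets,
                       trials: int = 100, seed: int | None = None,
                       engine: RankEngineConfig | None = None) -> tuple[float, int]:
    """Fraction of random-weight draws attaining full target rank.

    Every edge weight is redrawn i.i.d. uniform on (0.5, 1.5) per trial — the
    support avoids zero and tiny magnitudes so no structural zero is ever
    introduced.  Floats are dyadic rationals, so the default GF(p) engine
    maps them to residues exactly; the check stays exact per draw.

    Returns ``(pass_fraction, max_rank_seen)``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    D = as_selector(drivers, "driver")
    T = as_selector(targets, "target")
    engine = engine or RankEngineConfig(seed=seed)
    rng = np.random.default_rng(seed)
    m = len(T)
    passes = 0
    max_rank = 0
    for _ in range(trials):
        weights = [float(w) for w in rng.uniform(0.5, 1.5, size=net.edge_count)]
        A = state_matrix(net.with_weights(weights))
        r = control_matrix_rank(A, D, T, engine)
        max_rank = max(max_rank, r)
        if r == m:
            passes += 1
    return passes / trials, max_rank
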