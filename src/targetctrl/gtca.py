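"""Greedy feed-forward driver selection for exact target controllability.

The algorithm finds a small driver set D such that the output
controllability matrix CM(A, B_D, C_T) has full row rank |T| (Kalman's
condition for the targets).  It proceeds in three parts:

part one
    Seed D with the in-degree-0 targets (nothing upstream can drive them),
    credit D with the targets it already controls, remove the drivers'
    rows/columns from the working copy of A, and then repeatedly pick a new
    driver: scan the pure power blocks C_T A^i, keep the powers of minimum
    nonzero rank, collect their maximal independent columns as candidate
    vertices Y, and take the candidate y maximizing R(y) = rank CM(A, B_{y},
    C_T).  Targets controlled by y alone leave T; y leaves the working
    matrix and joins D.  The loop ends when T empties or no nonzero power
    block remains.

part two
    Per-target credit does not imply joint full rank (independent rows for
    different singleton drivers may collide).  On the ORIGINAL A and T, add
    uncontrolled targets themselves as drivers — the one raising the joint
    rank most — until CM(A, B_D, C_T) has rank |T|.  Each addition raises
    the rank by at least one (the new identity column makes that target's
    row independent), so termination is guaranteed.

part three
    Prune to 1-minimality: scan D in insertion order, drop any driver whose
    removal preserves full rank, and restart the scan after each drop.

The only run-to-run stochasticity is a seeded permutation of the vertex
ordering: greedy row/column scans walk that ordering ascending, and rank
ties are broken in favor of the candidate occupying the *latest* position.
A fixed seed reproduces the whole trace bit for bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from .network import (
    DirectedNetwork,
    StateMatrix,
    VertexSelector,
    as_selector,
    in_degree_zero_vertices,
    remove_vertices,
    state_matrix,
)
from .rank import (
    RankEngineConfig,
    control_matrix_rank,
    is_target_controllable,
    krylov_blocks,
    max_independent_cols,
    max_independent_rows,
    powers_min_rank,
)

__all__ = [
    "GTCAConfig",
    "GTCAState",
    "CandidateScore",
    "GTCAResult",
    "part_one",
    "select_candidate",
    "part_two",
    "part_three_prune",
    "run_gtca",
]


@dataclass(frozen=True)
class GTCAConfig:
    """Knobs of the greedy search.

    seed
        Seeds the vertex-ordering permutation (and, unless the engine has
        its own seed, the rank engine's prime draw).  ``None`` keeps the
        input ordering.
    engine
        Arithmetic backend for every rank decision.
    max_power
        Cap on the Krylov power range (default n-1); lowering it trades
        soundness for speed and is a testing hook only.
    """

    seed: int | None = None
    engine: RankEngineConfig = field(default_factory=RankEngineConfig)
    max_power: int | None = None

    def resolved_engine(self) -> RankEngineConfig:
        if self.engine.seed is None and self.seed is not None:
            return replace(self.engine, seed=self.seed)
        return self.engine


@dataclass
class CandidateScore:
    """A scored driver candidate y with provenance.

    ``rank`` is R(y) = rank CM(A, B_{y}, C_T) on the current working matrix
    and remaining targets; ``powers`` records which minimum-rank power
    blocks contributed y's column.
    """

    vertex: str
    rank: int
    powers: tuple[int, ...]


@dataclass
class GTCAState:
    """Mutable bookkeeping of part one."""

    network: DirectedNetwork          # working copy, drivers removed
    remaining: list[str]              # uncontrolled targets, in ordering
    drivers: list[str]                # insertion order
    controlled_log: list[dict]        # one entry per step that credited control


@dataclass
class GTCAResult:
    """Final driver set with the per-part trace of a seeded run."""

    drivers: tuple[str, ...]
    rank: int
    target_count: int
    trace: dict
    seed: int | None
    engine: RankEngineConfig

    def to_dict(self) -> dict:
        return {
            "drivers": list(self.drivers),
            "rank": self.rank,
            "target_count": self.target_count,
            "trace": self.trace,
            "seed": self.seed,
        }


def _ordering(net: DirectedNetwork, seed: int | None) -> list[str]:
    order = list(net.vertices)
    if seed is not None:
        random.Random(seed).shuffle(order)
    return order


def _sorted_by(order: Sequence[str], labels) -> list[str]:
    pos = {v: i for i, v in enumerate(order)}
    return sorted(labels, key=pos.__getitem__)


def select_candidate(A: StateMatrix, targets, config: GTCAConfig | None = None):
    """One greedy pick: scan power blocks, score candidates, break ties late.

    Returns a :class:`CandidateScore`, or ``None`` when every power block
    C_T A^i is zero (no vertex feeds the remaining targets through any
    walk), in which case part two resolves the leftovers by direct
    injection.
    """
    config = config or GTCAConfig()
    engine = config.resolved_engine()
    T = as_selector(targets, "target")
    scan = powers_min_rank(A, T, engine)
    if not scan.powers:
        return None
    provenance: dict[str, list[int]] = {}
    for i in scan.powers:
        for c in max_independent_cols(scan.matrix_for(i), engine):
            provenance.setdefault(A.labels[c], []).append(i)
    max_power = config.max_power if config.max_power is not None else A.n - 1
    best: CandidateScore | None = None
    for y in A.labels:  # ascending ordering; later equal scores overwrite
        if y not in provenance:
            continue
        r = control_matrix_rank(A, [y], T, engine, max_power=max_power)
        if best is None or r >= best.rank:
            best = CandidateScore(y, r, tuple(provenance[y]))
    return best


def part_one(net: DirectedNetwork, targets, config: GTCAConfig | None = None) -> GTCAState:
    """Seed with in-degree-0 targets, then greedily add feed-forward drivers.

    ``net`` must already carry the (possibly permuted) working ordering; T is
    kept sorted by that ordering so greedy row scans respect it.
    """
    config = config or GTCAConfig()
    engine = config.resolved_engine()
    T = as_selector(targets, "target")
    order = list(net.vertices)
    remaining = _sorted_by(order, T.labels)
    drivers: list[str] = []
    log: list[dict] = []
    work = net

    seeds = in_degree_zero_vertices(net, VertexSelector(tuple(remaining), "target"))
    if len(seeds):
        A = state_matrix(work)
        view = krylov_blocks(A, seeds, VertexSelector(tuple(remaining), "target"),
                             max_power=config.max_power, engine=engine)
        rows = max_independent_rows(view, engine)
        controlled = [remaining[i] for i in rows]
        log.append({"step": "seed", "drivers": list(seeds.labels),
                    "controlled": controlled})
        remaining = [t for t in remaining if t not in set(controlled)]
        drivers.extend(seeds.labels)
        if remaining:  # the working copy is only consulted while targets remain
            work = remove_vertices(work, seeds)

    while remaining:
        A = state_matrix(work)
        Tsel = VertexSelector(tuple(remaining), "target")
        cand = select_candidate(A, Tsel, config)
        if cand is None:
            break  # no walk reaches the leftovers; part two injects them
        view = krylov_blocks(A, [cand.vertex], Tsel,
                             max_power=config.max_power, engine=engine)
        rows = max_independent_rows(view, engine)
        controlled = [remaining[i] for i in rows]
        if not controlled:  # unreachable: a candidate column is nonzero
            break
        log.append({"step": "greedy", "driver": cand.vertex, "rank": cand.rank,
                    "powers": list(cand.powers), "controlled": controlled})
        remaining = [t for t in remaining if t not in set(controlled)]
        drivers.append(cand.vertex)
        if remaining:
            work = remove_vertices(work, [cand.vertex])

    return GTCAState(network=work, remaining=remaining, drivers=drivers,
                     controlled_log=log)


def part_two(net: DirectedNetwork, targets, drivers,
             config: GTCAConfig | None = None,
             trace: list | None = None) -> VertexSelector:
    """Augment D with targets until CM(A, B_D, C_T) reaches full rank |T|.

    Works on the ORIGINAL state matrix and target set: Kalman's condition is
    only meaningful on the full system, not on part one's shrunken copy.
    """
    config = config or GTCAConfig()
    engine = config.resolved_engine()
    A = state_matrix(net)
    order = list(net.vertices)
    T = VertexSelector(tuple(_sorted_by(order, as_selector(targets).labels)), "target")
    D = list(as_selector(drivers, "driver").labels)
    max_power = config.max_power if config.max_power is not None else A.n - 1

    rank = control_matrix_rank(A, D, T, engine, max_power=max_power) if D else 0
    while True:
        if D:
            view = krylov_blocks(A, VertexSelector(tuple(D), "driver"), T,
                                 max_power=config.max_power, engine=engine)
            rows = max_independent_rows(view, engine)
            controlled = {T.labels[i] for i in rows}
        else:
            controlled = set()
        uncontrolled = [t for t in T.labels if t not in controlled]
        if not uncontrolled:
            break
        best_t, best_rank = None, -1
        for t in uncontrolled:  # ascending ordering; ties keep the latest
            r = control_matrix_rank(A, D + [t], T, engine, max_power=max_power)
            if r >= best_rank:
                best_t, best_rank = t, r
        assert best_rank > rank, "part-two addition must raise the rank"
        D.append(best_t)
        rank = best_rank
        if trace is not None:
            trace.append({"added": best_t, "rank": rank})
    return VertexSelector(tuple(D), "driver")


def part_three_prune(net: DirectedNetwork, targets, drivers,
                     config: GTCAConfig | None = None,
                     trace: list | None = None) -> VertexSelector:
    """Drop drivers whose removal keeps full rank; restart after each drop.

    The input must already satisfy Kalman's condition for T; the output is
    1-minimal (no single driver can be removed).
    """
    config = config or GTCAConfig()
    engine = config.resolved_engine()
    A = state_matrix(net)
    T = as_selector(targets, "target")
    D = list(as_selector(drivers, "driver").labels)
    max_power = config.max_power if config.max_power is not None else A.n - 1
    m = len(T)
    if control_matrix_rank(A, D, T, engine, max_power=max_power) != m:
        raise ValueError("part three requires a full-rank driver set")
    i = 0
    while i < len(D):
        trial = D[:i] + D[i + 1:]
        if trial and control_matrix_rank(A, trial, T, engine, max_power=max_power) == m:
            if trace is not None:
                trace.append({"removed": D[i]})
            D = trial
            i = 0  # restart the scan
        else:
            i += 1
    return VertexSelector(tuple(D), "driver")


def run_gtca(net: DirectedNetwork, targets, config: GTCAConfig | None = None) -> GTCAResult:
    """Run all three parts and return a reproducible, 1-minimal driver set."""
    config = config or GTCAConfig()
    engine = config.resolved_engine()
    T = as_selector(targets, "target")
    for t in T:
        net.index(t)  # membership check
    if len(T) == 0:
        return GTCAResult((), 0, 0, {"ordering": list(net.vertices)}, config.seed, engine)

    order = _ordering(net, config.seed)
    work = net.reordered(order)
    trace: dict = {"ordering": order, "part_two_added": [], "part_three_removed": []}

    state = part_one(work, T, config)
    trace["part_one"] = state.controlled_log
    trace["part_one_drivers"] = list(state.drivers)
    trace["part_one_unresolved"] = list(state.remaining)

    D = part_two(work, T, state.drivers, config, trace["part_two_added"])
    D = part_three_prune(work, T, D, config, trace["part_three_removed"])

    A = state_matrix(work)
    rank = control_matrix_rank(A, D, T, engine,
                               max_power=config.max_power)
    return GTCAResult(tuple(D.labels), rank, len(T), trace, config.seed, engine)
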