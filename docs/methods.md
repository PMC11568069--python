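# Methods

## Model and problem

A directed weighted graph `G(V, E)` on `n` vertices induces the LTI system
`dx/dt = A x + B_D u`, `y = C_T x`, with `A` the transpose of the adjacency
matrix, `B_D` the identity columns of an ordered driver set `D`, and `C_T`
the identity rows of an ordered target set `T` (`m = |T|`). `D` exactly
controls `T` iff the output controllability matrix
`CM(A, B_D, C_T) = [C_T B_D | C_T A B_D | ... | C_T A^{n-1} B_D]` has rank
`m` (Kalman). With `T = V` this specializes to full-control Kalman rank.
Time-domain simulation of `x(t)` is out of scope: controllability is decided
algebraically.

Finding a minimum `D` is NP-hard in both the exact and structural settings,
so the package pairs greedy searches with verification (every returned exact
set is re-checked against Kalman's condition; every structural set against a
generic-rank certificate) and with oracles for small instances.

## Rank arithmetic

Entries of `A^i` count weighted walks and grow exponentially in `i`, so
float linear algebra misranks all but toy systems. Engines
(`RankEngineConfig`):

* **modp** (default): all elimination over GF(p) for a random 31-bit prime.
  A rank over GF(p) never exceeds the rational rank and falls below it only
  when p divides a critical minor, so agreement of two independent primes is
  a Monte-Carlo certificate; a disagreement draws a third prime and takes
  the majority, and a three-way split raises `NumericalIntegrityError`.
  Non-integer weights (rationals, floats — floats are dyadic rationals) map
  exactly to residues via modular inverses. Modular matmuls split operands
  into 16-bit halves so every partial product stays below 2^63 in int64.
* **rational**: incremental Fraction elimination; exact, slow; the oracle in
  tests.
* **svd**: float64 singular values with tolerance
  `max(dims) * eps * sigma_max` (overridable); a cross-check at small scale.

`CM` is never materialized with all `n` powers: Krylov blocks are built
iteratively (`K <- A K`) and the iteration stops as soon as the span of
`{B, AB, A^2 B, ...}` on the **full state** stops growing — by
Cayley–Hamilton all later blocks are linearly dependent, hence so are their
`C_T` projections. Early-stop equality with the full-power rank is asserted
on 100 seeded digraphs in the test suite.

Greedy "maximum independent rows/columns" scan ascending index and keep a
row/column iff it is independent of those already kept; the result size
always equals the matrix rank. When several maximal sets exist, the
ascending scan is the deterministic tie-break; the seeded vertex permutation
(below) is what re-randomizes it between runs.

## The greedy exact search (`run_gtca`)

Part one seeds `D` with the in-degree-0 targets (no walk can reach them, so
they must be driven directly), credits `D` with the targets whose rows are
independent in `CM(A, B_D, C_T)`, and deletes the drivers' rows and columns
from a working copy of `A` (labels are preserved throughout, so reported
drivers never go stale). It then iterates: scan the pure power blocks
`C_T A^i` for `i = 1..n-1`, keep the powers attaining the **minimum nonzero
rank** (an all-zero matrix has no independent columns to offer, so zero
blocks are excluded; if every power is zero the loop exits and part two
resolves the leftovers by direct injection — both readings are required for
the candidate step to be well defined and for termination), collect the
maximal-independent-column vertices of those blocks as candidates `Y`, score
each `y` by `R(y) = rank CM(A, B_{y}, C_T)`, and take the maximum, breaking
ties toward the **latest** position in the current vertex ordering. Targets
controlled by `y` alone (independent rows of its singleton CM, computed on
the current shrunken `A`) leave `T`; `y` leaves the matrix and joins `D`.
Each selected candidate controls at least one remaining target (its
harvested column is nonzero), so part one terminates.

Part two returns to the **original** `A` and `T` — per-target credit from
singleton matrices does not imply joint full rank, and Kalman's condition is
only meaningful on the full system. While uncontrolled targets exist (rows
outside the maximal independent set), the uncontrolled target whose addition
maximizes the joint rank is added to `D` (ties again to the latest
position). The new identity column makes that target's own row independent,
so every addition raises the rank by at least 1 (asserted per iteration) and
the loop terminates at rank `m`.

Part three prunes: scan `D` in insertion order, drop any driver whose
removal preserves full rank, and restart the scan after each drop. The
result is 1-minimal: no single driver can be removed. It is not guaranteed
globally minimal (NP-hardness); the suite measures the gap against the
exhaustive oracle (0 on the default 200-instance suite).

The single source of run-to-run stochasticity is a seeded permutation of
the vertex ordering applied before part one; it changes which rows/columns
the ascending greedy scans keep and which tied candidate is "latest". The
same degenerate guard applies throughout: the working copy is only
consulted while uncontrolled targets remain, so removals never empty the
network.

On the built-in 8-vertex example the greedy returns a size-4 set under every
ordering tested; which size-4 set (e.g. {1,3,7,8} vs {1,5,7,8}) depends only
on the tie-breaks, and the tests assert the size and the rank, not the
identity.

## Structural control

Full control uses the minimum input theorem: a maximum matching in the
bipartite out-copy/in-copy graph (Hopcroft–Karp, deterministic given the
ordering); unmatched in-copies are the drivers, a perfect matching gets one
free input assigned to the first vertex of the ordering. Note the theorem
counts *independent signals* and permits shared-signal attachments to
cycles that are otherwise inaccessible; with inputs restricted to plain
identity columns (as everywhere in this package), the unmatched-vertex set
can be insufficient for an inaccessible cycle, so the exhaustive
identity-column minimum is lower-bounded by — but need not equal — the
matching count. The tests assert exactly that bound.

Target structural control is a layered matching: match the current target
layer to in-neighbors (each in-neighbor carries at most one target per
layer — a single input can serve several targets only at distinct walk
lengths), unmatched layer members become drivers, matched predecessors not
already in the layer (or already drivers) form the next layer, and the layer
count is capped at `n` so cycles terminate (a capped layer is injected
directly). Pure layering is myopic around cycles and deep reconvergent
walks, so the result is refined under a **generic-rank certificate**: a
single random-weight realization whose control matrix reaches full rank
proves generic full rank (GF(p) rank ≤ rational rank ≤ generic rank), and a
failed draw can only keep the set conservative. Refinement = completion
(inject targets until a certificate exists), 1-minimal pruning, and 2-for-1
swaps (replace two drivers by one vertex when a certificate survives). This
refinement was adopted after the pure layering produced occasional driver
sets *larger* than the exact greedy's — contradicting the defining property
that exact control needs at least as many inputs as structural control on
the same pattern; with it, the ordering holds on every instance of the
random suite.

The two-step composition (`two_step`) feeds the exact drivers to the
structural stage as its targets: the exact stage certifies Kalman's
condition for `T`, the structural stage then reduces the external signals
needed to operate those drivers.

## Oracles

`brute_force_min_drivers` enumerates subsets by size (lexicographic in the
vertex ordering) until a full-rank subset appears, and returns all minimum
sets; it refuses `n > 12` by default. An optional candidate pool restricts
enumeration but is a heuristic prune (off by default).

`generic_rank_check` redraws every edge weight i.i.d. uniform on (0.5, 1.5)
— the support avoids zero and small magnitudes, so no structural zero is
introduced and the drawn floats map to GF(p) residues exactly — and reports
the fraction of draws attaining rank `m`, plus the maximum rank seen (the
empirical generic rank, which dominates the unit-weight rank).

## Synthetic networks and evaluation protocol

* Erdős–Rényi: each ordered pair (u ≠ v) is an edge with probability `p`,
  unit weights, numpy-seeded and bit-reproducible.
* Scale-free: preferential attachment from a 2-cycle seed; each new vertex
  sends `attachment` (default 2) edges to existing vertices chosen with
  probability proportional to in-degree + 1, yielding the heavy in-degree
  tail the generator exists to emulate.
* Target selection: uniform without replacement (`random`), or a
  breadth-first ball on the underlying undirected graph from a seeded start,
  restarting from a new random vertex when a component is exhausted
  (`local`). The BFS-ball reading of "local" is this package's own
  construction — no canonical definition exists — and results obtained with
  it should be labeled as such.
* `evaluate` runs an algorithm `repeats` times (default 20) with derived
  seeds `seed + i` (auditable), reporting per-run `|D|/|T|`, their mean and
  population SD, and the consensus driver set: vertices present in at least
  a threshold fraction of runs (default 0.9 — nine of ten).

These generators produce unit-weight, homogeneous (ER) or hub-dominated
(preferential-attachment) digraphs without the modularity, degree
correlations, autoregulation or weight heterogeneity of real biomolecular
networks; passing suites demonstrate algorithmic correctness and the
exact/structural ordering on such patterns, not performance claims on any
particular real network.

## Problem sizes and defaults

The bundled suites use 200 ER instances (n ≤ 8, edge probability 0.25,
|T| ≤ 4, unit weights) for the greedy-vs-oracle and ordering checks — sizes
at which the exhaustive oracle is exact — 500 random Krylov matrices of
dimension ≤ 12 for three-engine agreement, 100 digraphs (n ≤ 10) for
early-stop soundness, and a fixed asymmetric 20-vertex ER fixture
(p = 0.08) for determinism/variability demonstrations. The default engine
is modp with two primes; `max_power` defaults to `n−1`.

## Known limitations

* Greedy results are 1-minimal local optima, not global minima.
* The generic-rank certificate is one-sided Monte-Carlo: a certificate is a
  proof, a miss is only evidence; missed certificates make structural sets
  conservatively larger, never unsound.
* Exact Krylov block materialization (`krylov_blocks`) uses big-integer /
  rational arithmetic and is meant for inspection and testing; rank queries
  on larger networks should go through `control_matrix_rank`, which stays in
  GF(p) throughout.
* The structural swap refinement costs O(|D|² n) certificates per round and
  is intended for the moderate driver-set sizes typical of target control,
  not for full-control driver sets on very large sparse networks.
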