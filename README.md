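# targetctrl

Exact and structural **target controllability** of directed networks:
find a small set of *driver vertices* whose external input signals can steer
a designated subset of vertices — the *targets* — to any desired state.

Driver selection of this kind is used on biomolecular networks (protein–
protein interaction, signaling, gene-regulatory graphs), where driver
proteins are drug-target candidates and the targets are, e.g., disease-
associated or essential genes. Both full-network and target controllability
are NP-hard, so practical tools are greedy heuristics with verified output.

## The model

A directed weighted graph `G(V, E)` with `n = |V|` vertices defines the
linear time-invariant dynamics

```
dx/dt = A x(t) + B u(t),      y = C x(t)
```

where `A` is the **transpose of the adjacency matrix** (`a_ij` = weight of
the edge `v_j -> v_i`), a driver set `D = {d_0, ..., d_p-1}` gives the input
matrix `B_D = [I(d_0), ..., I(d_p-1)]` (identity columns), and a target set
`T = {c_0, ..., c_m-1}` gives the output matrix `C_T = [I(c_0); ...;
I(c_m-1)]` (identity rows). `D` controls `T` exactly iff the output
controllability matrix

```
CM(A, B_D, C_T) = [C_T B_D | C_T A B_D | C_T A^2 B_D | ... | C_T A^{n-1} B_D]
```

has full row rank `m` (Kalman's rank condition). *Structural* control asks
only that the rank condition hold for almost every numerical realization of
the zero/nonzero pattern; for full control the minimum number of inputs is
`max(n − |maximum matching|, 1)` (minimum input theorem).

The package provides:

* `run_gtca` — a three-part greedy feed-forward search for a 1-minimal exact
  driver set: seed with in-degree-0 targets, greedily add vertices scored by
  the rank of their singleton control matrix (candidates harvested from the
  minimum-rank power blocks `C_T A^i`), augment with uncontrolled targets to
  full rank, then prune;
* exact rank arithmetic — entries of `A^i` grow exponentially, so ranks are
  computed over GF(p) for two agreeing random 31-bit primes (Monte-Carlo
  exact), with exact-rational and float-SVD engines as cross-checks;
* `minimum_inputs_full` / `structural_target_control` — matching-based
  structural control, plus the **two-step composition** (`two_step`): the
  exact drivers become the structural stage's targets, compounding the
  input reduction;
* oracles (`brute_force_min_drivers`, `generic_rank_check`) and synthetic
  evaluation protocols (`gen_erdos_renyi`, `gen_scale_free`, random/local
  target selection, repeated seeded runs with consensus drivers).

## Worked example

The 8-vertex feed-forward network with edges 1→2, 4→3, 4→5, 6→3, 6→5, 7→4,
8→6 and targets {1,...,6} (`examples/01_worked_example.py`):

```python
import targetctrl as tc

net, targets = tc.feedforward_example()
result = tc.run_gtca(net, targets, tc.GTCAConfig(seed=1))
oracle = tc.brute_force_min_drivers(net, targets)
```

prints

```
greedy driver set : ('1', '7', '8', '3')  (|D| = 4)
achieved rank     : 6 of |T| = 6
oracle minimum    : 4 drivers; 8 minimum sets, e.g. ('1', '3', '4', '6')
```

Four drivers are necessary and sufficient for exact control of the six
targets, and the greedy attains that optimum. The three sources {1, 7, 8}
illustrate the structural/exact gap (`examples/02_exact_vs_structural.py`):
their unit-weight control matrix stalls at rank 5, yet 100% of random-weight
draws reach rank 6 — they control the targets structurally but fail Kalman's
condition, which is why the fourth driver is needed. The two-step
composition (`examples/04_two_step_composition.py`) then drives the four
exact drivers structurally with only three inputs (ratio 0.5 vs 0.667).

A thin CLI mirrors the library:

```
targetctrl gtca --edges edges.tsv --targets targets.txt --seed 1
targetctrl structural --edges edges.tsv --targets targets.txt
targetctrl twostep --edges edges.tsv --targets targets.txt --seed 1
targetctrl simulate er --n 100 --edge-prob 0.05 --seed 7
targetctrl evaluate --edges edges.tsv --targets-frac 0.5 --repeats 20 --seed 0
```

Edge lists are plain TSV/CSV (`source target [weight]`, `#` comments,
optional `%vertices:` header for isolated vertices); target lists are one
label per line.

## Layout

```
src/targetctrl/      library (network, rank, gtca, structural, oracle, synth)
examples/            one narrative script per capability
tests/               pytest suite (unit, property and end-to-end checks)
scripts/acceptance.py
docs/methods.md      model, algorithms, numerical choices, limitations
```
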