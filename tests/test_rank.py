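"""Krylov blocks, control-matrix ranks and independent row/column sets."""

import numpy as np
import pytest
import sympy

import targetctrl as tc
from targetctrl import (
    RankEngineConfig,
    control_matrix_rank,
    is_target_controllable,
    krylov_blocks,
    max_independent_cols,
    max_independent_rows,
    powers_min_rank,
)

ENGINES = [
    RankEngineConfig(method="modp", seed=11),
    RankEngineConfig(method="rational"),
    RankEngineConfig(method="svd"),
]


def chain(*labels):
    return tc.DirectedNetwork(tuple(labels),
                              tuple((labels[i], labels[i + 1], 1)
                                    for i in range(len(labels) - 1)))


def sympy_rank(view) -> int:
    """Independent oracle: exact rational rank via sympy."""
    M = view.matrix if isinstance(view, tc.ControlMatrixView) else view
    if M.size == 0:
        return 0
    return sympy.Matrix(M.tolist()).rank()


class TestKrylovBlocks:
    def test_feedforward_single_source(self, ff_net, ff_targets):
        A = tc.state_matrix(ff_net)
        view = krylov_blocks(A, ["1"], ff_targets)
        # walks from vertex 1: itself (power 0), vertex 2 (power 1), nothing after
        e1 = np.zeros((6, 1), dtype=object); e1[0, 0] = 1
        e2 = np.zeros((6, 1), dtype=object); e2[1, 0] = 1
        assert (view.blocks[0] == e1).all()
        assert (view.blocks[1] == e2).all()
        assert all(not b.any() for b in view.blocks[2:])

    def test_isolated_vertex_driver_and_target(self):
        net = tc.DirectedNetwork(("v", "w"), (("w", "w", 1),))
        view = krylov_blocks(tc.state_matrix(net), ["v"], ["v"])
        assert view.blocks[0][0, 0] == 1
        assert all(not b.any() for b in view.blocks[1:])

    def test_nilpotent_chain_block_appears_at_right_power(self):
        net = chain("1", "2", "3")
        view = krylov_blocks(tc.state_matrix(net), ["1"], ["3"], early_stop=False)
        assert [int(b[0, 0]) for b in view.blocks] == [0, 0, 1]

    def test_blocks_match_naive_multiplication(self, ff_net, ff_targets):
        A = tc.state_matrix(ff_net)
        D = ["1", "7"]
        view = krylov_blocks(A, D, ff_targets, early_stop=False)
        B = tc.b_matrix(A, D)
        C = tc.c_matrix(A, ff_targets)
        P = np.asarray(A.matrix)
        Ai = np.eye(ff_net.n, dtype=object)
        for blk in view.blocks:
            assert (blk == C @ Ai @ B).all()
            Ai = P @ Ai


class TestControlMatrixRank:
    @pytest.mark.parametrize("engine", ENGINES, ids=lambda e: e.method)
    def test_feedforward_full_rank_set(self, ff_net, ff_targets, engine):
        A = tc.state_matrix(ff_net)
        assert control_matrix_rank(A, ["1", "3", "7", "8"], ff_targets, engine) == 6

    @pytest.mark.parametrize("engine", ENGINES, ids=lambda e: e.method)
    def test_feedforward_structural_set_is_rank_deficient(self, ff_net, ff_targets, engine):
        # targets 3 and 5 receive identical walk patterns under unit weights
        A = tc.state_matrix(ff_net)
        assert control_matrix_rank(A, ["1", "7", "8"], ff_targets, engine) == 5

    def test_rank_matches_sympy_oracle(self, ff_net, ff_targets, modp):
        A = tc.state_matrix(ff_net)
        for D in (["1"], ["1", "7"], ["1", "7", "8"], ["2", "4"]):
            view = krylov_blocks(A, D, ff_targets, early_stop=False)
            assert control_matrix_rank(A, D, ff_targets, modp) == sympy_rank(view)

    def test_empty_driver_set_has_rank_zero(self, ff_net, ff_targets):
        assert control_matrix_rank(tc.state_matrix(ff_net), [], ff_targets) == 0

    def test_full_target_set_reproduces_kalman_matrix_rank(self, ff_net, modp):
        A = tc.state_matrix(ff_net)
        D = ["1", "7", "8"]
        view = krylov_blocks(A, D, ff_net.vertices, early_stop=False)
        assert control_matrix_rank(A, D, ff_net.vertices, modp) == sympy_rank(view)


class TestIsTargetControllable:
    def test_feedforward_verdicts(self, ff_net, ff_targets, modp):
        A = tc.state_matrix(ff_net)
        assert is_target_controllable(A, ["1", "3", "7", "8"], ff_targets, modp)
        assert not is_target_controllable(A, ["1", "7", "8"], ff_targets, modp)

    def test_self_driving_target(self, ff_net):
        A = tc.state_matrix(ff_net)
        for v in ff_net.vertices:
            assert is_target_controllable(A, [v], [v])

    def test_empty_target_set_rejected(self, ff_net):
        with pytest.raises(ValueError):
            is_target_controllable(tc.state_matrix(ff_net), ["1"], [])


class TestIndependentRowsCols:
    def test_identity_keeps_all_rows(self, rational):
        assert max_independent_rows(np.eye(3, dtype=int), rational) == [0, 1, 2]

    def test_duplicate_row_keeps_first(self, rational):
        M = np.array([[1, 2], [1, 2], [0, 1]], dtype=object)
        assert max_independent_rows(M, rational) == [0, 2]

    def test_zero_matrix_has_no_independent_cols(self, rational):
        assert max_independent_cols(np.zeros((3, 3), dtype=object), rational) == []

    def test_duplicate_col_keeps_first(self, rational):
        M = np.array([[1, 1, 0], [2, 2, 1]], dtype=object)
        assert max_independent_cols(M, rational) == [0, 2]

    def test_feedforward_dependent_target_row(self, ff_net, ff_targets, rational):
        # with drivers {1,7,8} the rows of targets 3 and 5 coincide; the
        # ascending scan keeps 3 and drops 5
        A = tc.state_matrix(ff_net)
        view = krylov_blocks(A, ["1", "7", "8"], ff_targets)
        rows = max_independent_rows(view, rational)
        assert [ff_targets.labels[i] for i in rows] == ["1", "2", "3", "4", "6"]

    def test_size_always_equals_rank(self, modp):
        rng = np.random.default_rng(5)
        for _ in range(30):
            M = rng.integers(-2, 3, size=rng.integers(1, 7, size=2)).astype(object)
            rows = max_independent_rows(M, modp)
            cols = max_independent_cols(M, modp)
            assert len(rows) == len(cols) == sympy_rank(M)


class TestPowersMinRank:
    def test_feedforward_after_seed_removal(self, ff_net, modp):
        sub = tc.remove_vertices(ff_net, ["1"])
        A = tc.state_matrix(sub)
        scan = powers_min_rank(A, ["3", "4", "5", "6"], modp)
        assert scan.powers == (2,)
        assert scan.min_rank == 1
        # the power-2 matrix has identical columns for the roots 7 and 8
        cols = tc.max_independent_cols(scan.matrix_for(2), modp)
        assert [A.labels[c] for c in cols] == ["7"]

    def test_edgeless_graph_has_no_nonzero_power(self):
        net = tc.DirectedNetwork(("a", "b", "c"))
        scan = powers_min_rank(tc.state_matrix(net), ["a", "b"])
        assert scan.powers == () and scan.min_rank == 0

    def test_self_loop_keeps_rank_one_at_every_power(self):
        net = tc.DirectedNetwork(("v", "w"), (("v", "v", 1),))
        scan = powers_min_rank(tc.state_matrix(net), ["v"])
        assert scan.powers == (1,) or scan.powers == tuple(range(1, net.n))
        assert scan.min_rank == 1


class TestEngineProperties:
    def test_engines_agree_on_random_krylov_matrices(self):
        rng = np.random.default_rng(42)
        engines = [RankEngineConfig("modp", seed=3), RankEngineConfig("rational"),
                   RankEngineConfig("svd")]
        for i in range(60):
            n = int(rng.integers(2, 9))
            net = tc.gen_erdos_renyi(n, 0.3, seed=int(rng.integers(1 << 30)))
            D = list(rng.choice(net.vertices, size=int(rng.integers(1, n + 1)), replace=False))
            T = list(rng.choice(net.vertices, size=int(rng.integers(1, n + 1)), replace=False))
            A = tc.state_matrix(net)
            ranks = {e.method: control_matrix_rank(A, D, T, e) for e in engines}
            assert len(set(ranks.values())) == 1, ranks

    def test_early_stop_equals_full_power_rank(self, modp, rational):
        rng = np.random.default_rng(17)
        for i in range(30):
            n = int(rng.integers(2, 11))
            net = tc.gen_erdos_renyi(n, 0.3, seed=int(rng.integers(1 << 30)))
            D = list(rng.choice(net.vertices, size=int(rng.integers(1, min(4, n + 1))),
                                replace=False))
            T = list(rng.choice(net.vertices, size=int(rng.integers(1, n + 1)), replace=False))
            A = tc.state_matrix(net)
            full = sympy_rank(krylov_blocks(A, D, T, early_stop=False))
            assert control_matrix_rank(A, D, T, modp) == full

    def test_adding_a_driver_never_decreases_rank(self, ff_net, ff_targets, modp):
        A = tc.state_matrix(ff_net)
        D = []
        prev = 0
        for v in ("8", "7", "3", "1", "2"):
            D.append(v)
            r = control_matrix_rank(A, D, ff_targets, modp)
            assert r >= prev
            prev = r

    def test_prime_disagreement_raises_integrity_error(self):
        # diag(6, 2) has rank 0 mod 2, 1 mod 3 and 2 mod 5: a three-way split
        bad = RankEngineConfig("modp", primes=(2, 3, 5))
        M = np.array([[6, 0], [0, 2]], dtype=object)
        with pytest.raises(tc.NumericalIntegrityError):
            max_independent_rows(M, bad)
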