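"""Controllability matrices (Krylov blocks) and exact rank computation.

Target controllability of the LTI system ``dx/dt = A x + B_D u`` with output
``y = C_T x`` is decided by the rank of the output controllability matrix

    CM(A, B_D, C_T) = [C_T B_D | C_T A B_D | ... | C_T A^{n-1} B_D]

(Kalman's condition: full control needs rank n of ``[B | AB | ... ]``; target
control needs full row rank m = |T|).  Entries of ``A^i`` count weighted walks
and grow exponentially with ``i``, which makes floating point unsound beyond
toy sizes.  The default engine therefore works in GF(p) for random 31-bit
primes p: ranks over GF(p) never exceed the rational rank and match it unless
p divides a critical minor, so agreement between two independent primes is a
Monte-Carlo certificate.  Exact rational elimination (the test oracle) and a
float SVD cross-check are also available.

Blocks are built iteratively (``K <- A K``) and the iteration stops early as
soon as the Krylov span ``span{B, AB, A^2 B, ...}`` of the *full state* stops
growing — by Cayley–Hamilton every later block is then linearly dependent on
the earlier ones, on the full state and hence also after projection by C_T.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence, Union

import numpy as np
import sympy

from .network import StateMatrix, VertexSelector, as_selector

__all__ = [
    "RankEngineConfig",
    "NumericalIntegrityError",
    "ControlMatrixView",
    "PowerScan",
    "get_engine",
    "krylov_blocks",
    "control_matrix_rank",
    "is_target_controllable",
    "max_independent_rows",
    "max_independent_cols",
    "powers_min_rank",
]


class NumericalIntegrityError(RuntimeError):
    """Independent arithmetic engines disagreed beyond the retry budget."""


@dataclass(frozen=True)
class RankEngineConfig:
    """How ranks are computed.

    method
        ``"modp"`` (default): Gaussian elimination over GF(p) for two random
        31-bit primes that must agree; a disagreement draws a third prime and
        takes the majority, and a three-way split raises
        :class:`NumericalIntegrityError`.
        ``"rational"``: exact Fraction elimination (slow, the oracle).
        ``"svd"``: float64 singular values with a scale-aware tolerance.
    primes
        Explicit moduli (testing hook); drawn from ``seed`` when empty.
    svd_tol
        Override for the SVD rank tolerance; default
        ``max(dims) * eps * sigma_max``.
    seed
        Seeds the prime draw; ``None`` gives fresh primes per engine.
    """

    method: str = "modp"
    primes: tuple[int, ...] = ()
    svd_tol: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("modp", "rational", "svd"):
            raise ValueError("method must be 'modp', 'rational' or 'svd'")


# ---------------------------------------------------------------------------
# GF(p) primitives
# ---------------------------------------------------------------------------

def _draw_prime(rng: random.Random) -> int:
    return int(sympy.nextprime(rng.randrange(2**30, 2**31 - 1)))


def _residue(x, p: int) -> int:
    f = Fraction(x)
    den = f.denominator % p
    if den == 0:
        raise NumericalIntegrityError(f"weight denominator divisible by modulus {p}")
    return f.numerator % p * pow(den, -1, p) % p


def _mod_matrix(M: np.ndarray, p: int) -> np.ndarray:
    out = np.zeros(M.shape, dtype=np.int64)
    flat_out = out.reshape(-1)
    for k, x in enumerate(M.reshape(-1)):
        if x:
            flat_out[k] = _residue(x, p)
    return out


def _matmul_mod(X: np.ndarray, Y: np.ndarray, p: int) -> np.ndarray:
    # int64-safe modular matmul: split X into 16-bit halves so partial
    # products stay below 2^63 for any 31-bit modulus.
    Xh, Xl = np.divmod(X, np.int64(1) << 16)
    return ((Xh @ Y % p) * ((1 << 16) % p) + Xl @ Y) % p


class _GFpBasis:
    """Incremental row-echelon basis over GF(p)."""

    def __init__(self, p: int):
        self.p = p
        self.rows: list[tuple[int, np.ndarray]] = []

    def add(self, v: np.ndarray) -> bool:
        p = self.p
        v = np.asarray(v, dtype=np.int64) % p
        for pivot, row in self.rows:
            c = v[pivot]
            if c:
                v = (v - c * row) % p
        nz = np.nonzero(v)[0]
        if nz.size == 0:
            return False
        piv = int(nz[0])
        v = v * pow(int(v[piv]), -1, p) % p
        self.rows.append((piv, v))
        return True

    @property
    def rank(self) -> int:
        return len(self.rows)


class _QBasis:
    """Incremental row-echelon basis over the rationals (exact)."""

    def __init__(self):
        self.rows: list[tuple[int, list[Fraction]]] = []

    def add(self, v) -> bool:
        v = [Fraction(x) for x in v]
        for pivot, row in self.rows:
            c = v[pivot]
            if c:
                v = [a - c * b for a, b in zip(v, row)]
        piv = next((i for i, x in enumerate(v) if x), None)
        if piv is None:
            return False
        inv = 1 / v[piv]
        self.rows.append((piv, [x * inv for x in v]))
        return True

    @property
    def rank(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

class _ModPEngine:
    def __init__(self, config: RankEngineConfig):
        self.config = config
        self._rng = random.Random(config.seed)
        self._primes = list(config.primes)

    def _prime(self, i: int) -> int:
        while len(self._primes) <= i:
            self._primes.append(_draw_prime(self._rng))
        return self._primes[i]

    def _agree(self, fn):
        a, b = fn(self._prime(0)), fn(self._prime(1))
        if a == b:
            return a
        c = fn(self._prime(2))
        if c == a or c == b:
            return c
        raise NumericalIntegrityError(
            "rank disagreement across three independent primes"
        )

    def matrix_rank(self, M: np.ndarray) -> int:
        if M.size == 0:
            return 0

        def rank_p(p: int) -> int:
            Mp = _mod_matrix(M, p)
            basis = _GFpBasis(p)
            for i in range(Mp.shape[0]):
                basis.add(Mp[i])
            return basis.rank

        return self._agree(rank_p)

    def independent_rows(self, M: np.ndarray) -> list[int]:
        if M.size == 0:
            return []

        def rows_p(p: int) -> tuple[int, ...]:
            Mp = _mod_matrix(M, p)
            basis = _GFpBasis(p)
            return tuple(i for i in range(Mp.shape[0]) if basis.add(Mp[i]))

        return list(self._agree(rows_p))

    def independent_cols(self, M: np.ndarray) -> list[int]:
        return self.independent_rows(M.T)

    def cm_rank(self, A: np.ndarray, d_idx: Sequence[int], t_idx: Sequence[int],
                max_power: int) -> int:
        if not d_idx:
            return 0

        def rank_p(p: int) -> int:
            n = A.shape[0]
            Ap = _mod_matrix(A, p)
            K = np.zeros((n, len(d_idx)), dtype=np.int64)
            for j, i in enumerate(d_idx):
                K[i, j] = 1
            t = np.asarray(t_idx, dtype=np.intp)
            state = _GFpBasis(p)
            cm = _GFpBasis(p)
            for power in range(max_power + 1):
                grew = False
                for j in range(K.shape[1]):
                    cm.add(K[t, j])
                    if state.add(K[:, j]):
                        grew = True
                if not grew or power == max_power:
                    break
                K = _matmul_mod(Ap, K, p)
            return cm.rank

        return self._agree(rank_p)


class _RationalEngine:
    def __init__(self, config: RankEngineConfig):
        self.config = config

    def matrix_rank(self, M: np.ndarray) -> int:
        if M.size == 0:
            return 0
        basis = _QBasis()
        for i in range(M.shape[0]):
            basis.add(M[i])
        return basis.rank

    def independent_rows(self, M: np.ndarray) -> list[int]:
        if M.size == 0:
            return []
        basis = _QBasis()
        return [i for i in range(M.shape[0]) if basis.add(M[i])]

    def independent_cols(self, M: np.ndarray) -> list[int]:
        return self.independent_rows(M.T)

    def cm_rank(self, A: np.ndarray, d_idx: Sequence[int], t_idx: Sequence[int],
                max_power: int) -> int:
        if not d_idx:
            return 0
        n = A.shape[0]
        K = np.zeros((n, len(d_idx)), dtype=object)
        for j, i in enumerate(d_idx):
            K[i, j] = 1
        t = list(t_idx)
        state = _QBasis()
        cm = _QBasis()
        for power in range(max_power + 1):
            grew = False
            for j in range(K.shape[1]):
                cm.add([K[i, j] for i in t])
                if state.add(K[:, j]):
                    grew = True
            if not grew or power == max_power:
                break
            K = A @ K
        return cm.rank


class _SVDEngine:
    def __init__(self, config: RankEngineConfig):
        self.config = config

    def _tol(self, M: np.ndarray, smax: float) -> float:
        if self.config.svd_tol is not None:
            return self.config.svd_tol
        return max(M.shape) * np.finfo(np.float64).eps * smax

    def matrix_rank(self, M: np.ndarray) -> int:
        if M.size == 0:
            return 0
        Mf = np.asarray(M, dtype=np.float64)
        s = np.linalg.svd(Mf, compute_uv=False)
        if s.size == 0 or s[0] == 0.0:
            return 0
        return int(np.sum(s > self._tol(Mf, float(s[0]))))

    def independent_rows(self, M: np.ndarray) -> list[int]:
        # greedy by row index: keep a row iff it raises the float rank
        out: list[int] = []
        kept: list[np.ndarray] = []
        Mf = np.asarray(M, dtype=np.float64)
        for i in range(Mf.shape[0]):
            trial = np.vstack(kept + [Mf[i]])
            if self.matrix_rank(trial) > len(out):
                out.append(i)
                kept.append(Mf[i])
        return out

    def independent_cols(self, M: np.ndarray) -> list[int]:
        return self.independent_rows(np.asarray(M).T)

    def cm_rank(self, A: np.ndarray, d_idx: Sequence[int], t_idx: Sequence[int],
                max_power: int) -> int:
        if not d_idx:
            return 0
        n = A.shape[0]
        Af = np.asarray(A, dtype=np.float64)
        K = np.zeros((n, len(d_idx)))
        for j, i in enumerate(d_idx):
            K[i, j] = 1.0
        t = np.asarray(t_idx, dtype=np.intp)
        blocks = [K[t, :]]
        for _ in range(max_power):
            K = Af @ K
            blocks.append(K[t, :])
        return self.matrix_rank(np.hstack(blocks))


_ENGINES = {"modp": _ModPEngine, "rational": _RationalEngine, "svd": _SVDEngine}


def get_engine(config: RankEngineConfig | None = None):
    config = config or RankEngineConfig()
    return _ENGINES[config.method](config)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _as_config(engine) -> RankEngineConfig:
    if engine is None:
        return RankEngineConfig()
    if isinstance(engine, RankEngineConfig):
        return engine
    return engine.config  # an engine instance


def _resolve(A: StateMatrix, sel, role: str) -> tuple[VertexSelector, list[int]]:
    s = as_selector(sel, role)
    return s, s.indices(A)


@dataclass
class ControlMatrixView:
    """The Krylov-block form of CM(A, B_D, C_T).

    ``blocks[i]`` equals ``C_T A^i B_D`` entrywise with exact arithmetic.
    The block list may stop before power n-1 when the full-state Krylov span
    stops growing (the remaining blocks add no rank).
    """

    blocks: list[np.ndarray]
    m: int
    p: int
    engine: RankEngineConfig = field(default_factory=RankEngineConfig)
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    @property
    def matrix(self) -> np.ndarray:
        if not self.blocks:
            return np.zeros((self.m, 0), dtype=object)
        return np.hstack(self.blocks)

    @property
    def rank(self) -> int:
        return get_engine(self.engine).matrix_rank(self.matrix)


def krylov_blocks(A: StateMatrix, drivers, targets, max_power: int | None = None,
                  engine: RankEngineConfig | None = None,
                  early_stop: bool = True) -> ControlMatrixView:
    """Exact blocks ``C_T A^i B_D`` for i = 0 .. max_power (default n-1).

    Early stopping is tracked on the full-state Krylov span with exact
    rational arithmetic, never on the C_T-projection.  Exact entries grow
    with walk counts; for large dense networks prefer
    :func:`control_matrix_rank`, which works in GF(p) throughout.
    """
    D, d_idx = _resolve(A, drivers, "driver")
    T, t_idx = _resolve(A, targets, "target")
    n = A.n
    if max_power is None:
        max_power = n - 1
    if max_power > n - 1:
        raise ValueError("max_power cannot exceed n-1")
    blocks: list[np.ndarray] = []
    if d_idx:
        K = np.zeros((n, len(d_idx)), dtype=object)
        for j, i in enumerate(d_idx):
            K[i, j] = 1
        state = _QBasis()
        for power in range(max_power + 1):
            blocks.append(K[t_idx, :].copy())
            grew = False
            for j in range(K.shape[1]):
                if state.add(K[:, j]):
                    grew = True
            if early_stop and not grew:
                break
            if power < max_power:
                K = A.matrix @ K
    return ControlMatrixView(
        blocks, m=len(t_idx), p=len(d_idx),
        engine=engine or RankEngineConfig(),
        row_labels=T.labels, col_labels=D.labels,
    )


def control_matrix_rank(A: StateMatrix, drivers, targets,
                        engine: RankEngineConfig | None = None,
                        max_power: int | None = None) -> int:
    """rank CM(A, B_D, C_T) under the chosen arithmetic engine.

    With ``targets`` equal to the full vertex set this is the Kalman matrix
    rank for full control.  An empty driver set has rank 0.
    """
    _, d_idx = _resolve(A, drivers, "driver")
    _, t_idx = _resolve(A, targets, "target")
    if max_power is None:
        max_power = A.n - 1
    return get_engine(engine).cm_rank(A.matrix, d_idx, t_idx, max_power)


def is_target_controllable(A: StateMatrix, drivers, targets,
                           engine: RankEngineConfig | None = None) -> bool:
    """Kalman's condition for the target set: rank CM = |T|."""
    T = as_selector(targets, "target")
    if len(T) == 0:
        raise ValueError("target set must be nonempty")
    return control_matrix_rank(A, drivers, T, engine) == len(T)


def _view_matrix(view_or_matrix) -> tuple[np.ndarray, RankEngineConfig | None]:
    if isinstance(view_or_matrix, ControlMatrixView):
        return view_or_matrix.matrix, view_or_matrix.engine
    return np.asarray(view_or_matrix, dtype=object), None


def max_independent_rows(view_or_matrix, engine: RankEngineConfig | None = None) -> list[int]:
    """Greedy maximal independent row set, scanning rows in ascending index.

    A row joins the set iff it is linearly independent of the rows already
    selected; the result size equals the matrix rank.  The ascending-index
    scan is the deterministic tie-break that the seeded vertex permutation
    re-randomizes.
    """
    M, cfg = _view_matrix(view_or_matrix)
    return get_engine(engine or cfg).independent_rows(M)


def max_independent_cols(view_or_matrix, engine: RankEngineConfig | None = None) -> list[int]:
    """Column analogue of :func:`max_independent_rows`."""
    M, cfg = _view_matrix(view_or_matrix)
    return get_engine(engine or cfg).independent_cols(M)


@dataclass
class PowerScan:
    """Result of scanning ranks of C_T A^i for i = 1 .. n-1.

    ``powers`` holds the exponents attaining the minimum *nonzero* rank
    (all-zero matrices have no independent columns to offer and are
    excluded); empty when every power vanishes on the targets.
    """

    powers: tuple[int, ...]
    min_rank: int
    matrices: dict[int, np.ndarray]

    def matrix_for(self, power: int) -> np.ndarray:
        return self.matrices[power]


def powers_min_rank(A: StateMatrix, targets,
                    engine: RankEngineConfig | None = None) -> PowerScan:
    """Find the powers i in 1..n-1 where rank(C_T A^i) is minimal (nonzero).

    The scan starts at i = 1 (the first pure power block, C_T A) and stops
    at the first exactly-zero power: each matrix is the previous one
    multiplied by A on the right, so once C_T A^i = 0 every later power
    vanishes too.
    """
    T, t_idx = _resolve(A, targets, "target")
    eng = get_engine(engine)
    n = A.n
    P = A.matrix[t_idx, :].copy()  # C_T A^1
    ranks: dict[int, int] = {}
    mats: dict[int, np.ndarray] = {}
    for i in range(1, n):
        if not P.any():
            break
        ranks[i] = eng.matrix_rank(P)
        mats[i] = P
        if i < n - 1:
            P = P @ A.matrix
    nonzero = {i: r for i, r in ranks.items() if r > 0}
    if not nonzero:
        return PowerScan((), 0, {})
    mr = min(nonzero.values())
    powers = tuple(i for i, r in nonzero.items() if r == mr)
    return PowerScan(powers, mr, {i: mats[i] for i in powers})
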