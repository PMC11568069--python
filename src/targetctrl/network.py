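"""Directed-network container, state-matrix construction and edge-list I/O.

The linear time-invariant dynamics ``dx/dt = A x + B u`` are read off a
directed weighted graph: the state matrix ``A`` is the *transpose* of the
graph's adjacency matrix, so ``A[i, j]`` holds the weight of the edge
``v_j -> v_i``.  Driver and target subsets are represented as ordered
:class:`VertexSelector` objects; as a driver set ``D`` they stand for the
input matrix ``B_D`` (columns of the identity), as a target set ``T`` for
the output matrix ``C_T`` (rows of the identity).

Vertex labels are opaque strings and every matrix carries an explicit label
map, so removing rows/columns during the greedy search never invalidates the
labels reported for driver vertices.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

Weight = Union[int, float, Fraction]

__all__ = [
    "DirectedNetwork",
    "StateMatrix",
    "VertexSelector",
    "EdgeListFormatError",
    "read_edge_list",
    "write_edge_list",
    "read_target_list",
    "state_matrix",
    "b_matrix",
    "c_matrix",
    "in_degree_zero_vertices",
    "remove_vertices",
    "reverse",
]


class EdgeListFormatError(ValueError):
    """An edge-list document violates the expected layout."""


@dataclass(frozen=True)
class DirectedNetwork:
    """A labeled directed weighted graph.

    Parameters
    ----------
    vertices
        Ordered, unique string labels.  The order defines "the ordering
        between the vertices" used everywhere downstream (matrix indices,
        greedy tie-breaking).
    edges
        Ordered ``(source, target, weight)`` triples.  Duplicate
        ``(source, target)`` pairs and zero weights are rejected; self-loops
        are legitimate dynamics terms and allowed.
    """

    vertices: tuple[str, ...]
    edges: tuple[tuple[str, str, Weight], ...] = ()

    def __post_init__(self) -> None:
        if len(self.vertices) < 1:
            raise ValueError("a network needs at least one vertex")
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("vertex labels must be unique")
        vset = set(self.vertices)
        seen: set[tuple[str, str]] = set()
        for u, v, w in self.edges:
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u!r}, {v!r}) references an unlisted vertex")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            if w == 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has zero weight")
            seen.add((u, v))
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.vertices)})

    # -- basic queries ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown vertex {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index  # type: ignore[attr-defined]

    def predecessors(self, label: str) -> tuple[str, ...]:
        return tuple(u for u, v, _ in self.edges if v == label)

    def successors(self, label: str) -> tuple[str, ...]:
        return tuple(v for u, v, _ in self.edges if u == label)

    def in_degree(self, label: str) -> int:
        return sum(1 for _, v, _ in self.edges if v == label)

    def with_weights(self, weights: Sequence[Weight]) -> "DirectedNetwork":
        """Same topology, new weights (in edge insertion order)."""
        if len(weights) != len(self.edges):
            raise ValueError("need one weight per edge")
        return DirectedNetwork(
            self.vertices,
            tuple((u, v, w) for (u, v, _), w in zip(self.edges, weights)),
        )

    def reordered(self, vertices: Sequence[str]) -> "DirectedNetwork":
        """Same graph with a permuted vertex ordering."""
        if sorted(vertices) != sorted(self.vertices):
            raise ValueError("reordering must be a permutation of the vertex set")
        return DirectedNetwork(tuple(vertices), self.edges)


@dataclass(frozen=True)
class VertexSelector:
    """An ordered vertex subset acting as a driver set D or target set T.

    As a driver set it denotes the input matrix ``B_D`` whose columns are
    identity columns ``I(d_i)``; as a target set, the output matrix ``C_T``
    whose rows are identity rows ``I(c_i)``.
    """

    labels: tuple[str, ...]
    role: str = "target"  # "driver" | "target"

    def __post_init__(self) -> None:
        if self.role not in ("driver", "target"):
            raise ValueError("role must be 'driver' or 'target'")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("selector labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def indices(self, order: Union["DirectedNetwork", "StateMatrix", Sequence[str]]) -> list[int]:
        """Positions of the selected labels in a network/matrix ordering."""
        if isinstance(order, (DirectedNetwork, StateMatrix)):
            return [order.index(lab) for lab in self.labels]
        pos = {v: i for i, v in enumerate(order)}
        return [pos[lab] for lab in self.labels]


def as_selector(labels, role: str = "target") -> VertexSelector:
    """Coerce a VertexSelector or an iterable of labels into a selector."""
    if isinstance(labels, VertexSelector):
        if labels.role == role:
            return labels
        return VertexSelector(labels.labels, role)
    return VertexSelector(tuple(labels), role)


@dataclass(frozen=True)
class StateMatrix:
    """The state matrix A with its label map.

    ``matrix[i, j]`` is the weight of the edge ``v_j -> v_i``, i.e. A is the
    transpose of the adjacency matrix.  Entries are exact Python numbers
    (int / Fraction; floats are tolerated) held in an object array so that
    downstream arithmetic never silently overflows.
    """

    matrix: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.labels)})

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def state_matrix(net: DirectedNetwork) -> StateMatrix:
    """Build A (transpose of the adjacency matrix) from a network."""
    n = net.n
    A = np.zeros((n, n), dtype=object)
    for u, v, w in net.edges:
        A[net.index(v), net.index(u)] = w
    return StateMatrix(A, net.vertices)


def b_matrix(order: Union[DirectedNetwork, StateMatrix], drivers) -> np.ndarray:
    """Input matrix B_D: one identity column per driver, in driver order."""
    D = as_selector(drivers, "driver")
    n = order.n
    B = np.zeros((n, len(D)), dtype=object)
    for j, i in enumerate(D.indices(order)):
        B[i, j] = 1
    return B


def c_matrix(order: Union[DirectedNetwork, StateMatrix], targets) -> np.ndarray:
    """Output matrix C_T: one identity row per target, in target order."""
    T = as_selector(targets, "target")
    n = order.n
    C = np.zeros((len(T), n), dtype=object)
    for i, j in enumerate(T.indices(order)):
        C[i, j] = 1
    return C


def reverse(net: DirectedNetwork) -> DirectedNetwork:
    """The network with every edge direction flipped."""
    return DirectedNetwork(net.vertices, tuple((v, u, w) for u, v, w in net.edges))


# ---------------------------------------------------------------------------
# graph surgery
# ---------------------------------------------------------------------------

def in_degree_zero_vertices(net: DirectedNetwork, targets) -> VertexSelector:
    """Targets with no incoming edge (they can only be driven directly)."""
    T = as_selector(targets, "target")
    for t in T:
        net.index(t)  # membership check
    has_in = {v for _, v, _ in net.edges}
    return VertexSelector(tuple(t for t in T if t not in has_in), "target")


def remove_vertices(net: DirectedNetwork, remove) -> DirectedNetwork:
    """Drop a vertex subset and every incident edge; survivors keep labels.

    Removing every vertex is an error: the empty network is not a valid
    state-space.
    """
    S = set(as_selector(remove).labels)
    unknown = S - set(net.vertices)
    if unknown:
        raise ValueError(f"cannot remove unlisted vertices: {sorted(unknown)}")
    survivors = tuple(v for v in net.vertices if v not in S)
    if not survivors:
        raise ValueError("removal would leave an empty network")
    edges = tuple(e for e in net.edges if e[0] not in S and e[1] not in S)
    return DirectedNetwork(survivors, edges)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_weight(token: str) -> Weight:
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return Fraction(token)
    except ValueError:
        return float(token)


def _split_fields(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",") if f.strip()]
    return line.split()


def read_edge_list(source, strict: bool = True) -> DirectedNetwork:
    """Read a TSV/CSV edge list into a :class:`DirectedNetwork`.

    Each non-comment line holds ``source target [weight]``; ``#`` starts a
    comment; an optional ``%vertices:`` header enumerates the full vertex
    list (needed for isolated vertices) and fixes the ordering.  Without a
    header, vertices appear in first-appearance order and weights default
    to 1.

    ``source`` may be a path, an open text handle, or a string containing
    newlines (treated as the document itself).

    In strict mode a duplicate ``(source, target)`` pair is a format error;
    in lenient mode the last occurrence wins.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and "\n" not in str(source) and Path(source).exists():
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = Path(source).read_text()

    explicit: list[str] | None = None
    order: list[str] = []
    seen_v: set[str] = set()
    edges: dict[tuple[str, str], Weight] = {}
    edge_order: list[tuple[str, str]] = []

    def note_vertex(v: str) -> None:
        if v not in seen_v:
            seen_v.add(v)
            order.append(v)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("%vertices:"):
            if explicit is not None:
                raise EdgeListFormatError(f"line {lineno}: repeated %vertices: header")
            explicit = _split_fields(line[len("%vertices:"):])
            continue
        fields = _split_fields(line)
        if len(fields) not in (2, 3):
            raise EdgeListFormatError(
                f"line {lineno}: expected 2 or 3 fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        w: Weight = _parse_weight(fields[2]) if len(fields) == 3 else 1
        if explicit is not None:
            if u not in explicit or v not in explicit:
                raise EdgeListFormatError(
                    f"line {lineno}: edge ({u}, {v}) references a vertex missing "
                    "from the %vertices: header"
                )
        if (u, v) in edges:
            if strict:
                raise EdgeListFormatError(f"line {lineno}: duplicate edge ({u}, {v})")
            edges[(u, v)] = w  # lenient: last occurrence wins
            continue
        note_vertex(u)
        note_vertex(v)
        edges[(u, v)] = w
        edge_order.append((u, v))

    vertices = tuple(explicit) if explicit is not None else tuple(order)
    try:
        return DirectedNetwork(vertices, tuple((u, v, edges[(u, v)]) for u, v in edge_order))
    except ValueError as exc:
        raise EdgeListFormatError(str(exc)) from exc


def write_edge_list(net: DirectedNetwork, path=None) -> str:
    """Serialize a network; the text round-trips bit-exactly through
    :func:`read_edge_list` (the ``%vertices:`` header pins the ordering)."""
    lines = ["%vertices: " + " ".join(net.vertices)]
    for u, v, w in net.edges:
        lines.append(f"{u}\t{v}" if w == 1 else f"{u}\t{v}\t{w}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_target_list(source) -> VertexSelector:
    """Read a target list: one label per line, '#' comments."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        text = Path(source).read_text()
    labels = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            labels.append(line)
    return VertexSelector(tuple(labels), "target")
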