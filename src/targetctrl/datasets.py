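"""Small built-in networks used throughout the docs and tests."""

from __future__ import annotations

from .network import DirectedNetwork, VertexSelector
from .synth import gen_erdos_renyi

__all__ = ["feedforward_example", "stochasticity_fixture"]


def feedforward_example() -> tuple[DirectedNetwork, VertexSelector]:
    """The 8-vertex, 7-edge feed-forward demonstration network.

    Edges: (1,2), (4,3), (4,5), (6,3), (6,5), (7,4), (8,6); targets 1–6.
    Exact control of the targets needs four drivers (e.g. {1, 3, 7, 8}),
    while the three sources {1, 7, 8} control them structurally but fail
    Kalman's rank condition under unit weights.
    """
    net = DirectedNetwork(
        tuple(str(i) for i in range(1, 9)),
        tuple((u, v, 1) for u, v in
              [("1", "2"), ("4", "3"), ("4", "5"),
               ("6", "3"), ("6", "5"), ("7", "4"), ("8", "6")]),
    )
    targets = VertexSelector(tuple(str(i) for i in range(1, 7)), "target")
    return net, targets


def stochasticity_fixture() -> tuple[DirectedNetwork, VertexSelector]:
    """An asymmetric 20-vertex digraph whose greedy driver set depends on the
    seeded vertex ordering — used to exercise run-to-run variability."""
    net = gen_erdos_renyi(20, 0.08, seed=2020)
    targets = VertexSelector(net.vertices[:10], "target")
    return net, targets
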