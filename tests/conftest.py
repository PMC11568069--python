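import pytest
from hypothesis import settings

import targetctrl as tc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ff_net():
    net, _ = tc.feedforward_example()
    return net


@pytest.fixture(scope="session")
def ff_targets():
    _, targets = tc.feedforward_example()
    return targets


@pytest.fixture(scope="session")
def modp():
    return tc.RankEngineConfig(method="modp", seed=7)


@pytest.fixture(scope="session")
def rational():
    return tc.RankEngineConfig(method="rational")


@pytest.fixture(scope="session")
def svd():
    return tc.RankEngineConfig(method="svd")


def make_random_digraph(n: int, edge_prob: float, seed: int):
    """Unit-weight random digraph used across property tests."""
    return tc.gen_erdos_renyi(n, edge_prob, seed=seed)
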