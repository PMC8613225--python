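import numpy as np
import pytest

from spreadrank import Graph, GenSpec, fixture, generate


@pytest.fixture
def path3():
    return fixture("path3")


@pytest.fixture
def star4():
    return fixture("star4")


@pytest.fixture
def cycle5():
    return fixture("cycle5")


@pytest.fixture
def complete5():
    return fixture("complete5")


@pytest.fixture
def two_stars_bridge():
    return fixture("two_stars_bridge")


def random_graph(seed: int, n: int, p: float) -> Graph:
    """Small seeded ER graph for oracle comparisons."""
    return generate(GenSpec("er", {"n": n, "p": p}, rng_seed=seed))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
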