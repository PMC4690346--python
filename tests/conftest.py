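import hypothesis
import numpy as np
import pytest

from multiplexcd import Graph, Multiplex

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def two_triangles() -> Graph:
    """Two disjoint triangles: the textbook unambiguous two-community graph."""
    return Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def triangle_partition() -> dict:
    return {0: "a", 1: "a", 2: "a", 3: "b", 4: "b", 5: "b"}


@pytest.fixture
def small_multiplex() -> Multiplex:
    """Two layers over a shared 4-vertex universe, one edge each."""
    return Multiplex(
        [Graph([(1, 2)], nodes=[1, 2, 3, 4]), Graph([(3, 4)], nodes=[1, 2, 3, 4])]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20151)
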