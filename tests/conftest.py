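import numpy as np
import pytest

from bacon import ConstraintGraph, InteractionCounts


@pytest.fixture
def two_successor_graph():
    """One source node with two possible successors."""
    return ConstraintGraph(["i", "a", "b"], [("i", "a"), ("i", "b")])


@pytest.fixture
def triangle_graph():
    """Directed 3-cycle a->b->c->a plus reverse edges."""
    nodes = ["a", "b", "c"]
    edges = [("a", "b"), ("b", "c"), ("c", "a"), ("b", "a"), ("c", "b"), ("a", "c")]
    return ConstraintGraph(nodes, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_counts(pairs):
    return InteractionCounts(pairs)
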