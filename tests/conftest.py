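import numpy as np
import pytest

from ppirank.network_io import graph_from_edges
from ppirank.synthetic import sbm_graph


@pytest.fixture
def two_cliques():
    """Two disjoint 5-cliques: the minimal community-structure testbed."""
    nodes_a = [f"a{i}" for i in range(5)]
    nodes_b = [f"b{i}" for i in range(5)]
    edges = [(u, v) for grp in (nodes_a, nodes_b) for u in grp for v in grp if u < v]
    return graph_from_edges(edges)


@pytest.fixture
def small_sbm():
    """A modest planted-partition graph for mid-weight tests."""
    return sbm_graph([40, 40], p_in=0.35, p_out=0.02, seed=11)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))
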