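import numpy as np
import pytest

from gdvb.contact_graph import ContactGraph
from gdvb.synthetic import FIG2_NODES, fig2_graph, point_model


@pytest.fixture(scope="session")
def fig2():
    return fig2_graph()


@pytest.fixture(scope="session")
def fig2_index():
    """Node label (A..I) -> index map for the worked-example graph."""
    return {c: i for i, c in enumerate(FIG2_NODES)}


@pytest.fixture
def chain3_model():
    """Three atoms on a line at 0, 1.5 and 3.0 Å."""
    return point_model(np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]]))


def make_graph(n, edges):
    return ContactGraph(n_nodes=n, edges=np.array(edges, dtype=np.int64).reshape(-1, 2))


@pytest.fixture(scope="session")
def named_small_graphs():
    """K3, K4, paths, cycles and stars with known structure."""
    return {
        "K3": make_graph(3, [(0, 1), (0, 2), (1, 2)]),
        "K4": make_graph(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]),
        "P4": make_graph(4, [(0, 1), (1, 2), (2, 3)]),
        "P6": make_graph(6, [(i, i + 1) for i in range(5)]),
        "C4": make_graph(4, [(0, 1), (1, 2), (2, 3), (0, 3)]),
        "C5": make_graph(5, [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]),
        "star5": make_graph(6, [(0, i) for i in range(1, 6)]),
        "paw": make_graph(4, [(0, 1), (1, 2), (0, 2), (2, 3)]),
        "diamond": make_graph(4, [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)]),
    }
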