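import numpy as np
import pytest

from vesselreg.graphio import VesselGraph, VesselNode


def build_graph(positions, edges, radii=None, ids=None):
    """Small-graph helper: positions as a list of tuples, edges as id pairs."""
    g = VesselGraph()
    n = len(positions)
    ids = list(range(n)) if ids is None else ids
    radii = [1.0] * n if radii is None else radii
    for i, p, r in zip(ids, positions, radii):
        g.add_node(VesselNode(i, tuple(float(c) for c in p), float(r)))
    for a, b in edges:
        g.add_edge(a, b)
    return g


@pytest.fixture
def path3():
    """A-B-C path, unit radii, unit spacing along x."""
    return build_graph([(0, 0), (1, 0), (2, 0)], [(0, 1), (1, 2)])


@pytest.fixture
def star3():
    """Center node 0 with three unit-radius leaves."""
    return build_graph(
        [(0, 0), (1, 0), (-1, 0), (0, 1)], [(0, 1), (0, 2), (0, 3)]
    )


@pytest.fixture
def tree():
    """Default synthetic tree (shared across tests; regenerating is cheap)."""
    from vesselreg.synthetic import TreeConfig, generate_tree

    return generate_tree(TreeConfig(seed=42))
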