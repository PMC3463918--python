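import numpy as np
import pytest

from vasctree.core import Edge, Node, VascularTree
from vasctree.synth import SyntheticPopulationSpec, make_perfect_tree, make_population


def build_tree(node_positions, edge_specs, root):
    """Helper: nodes as {id: (x,y,z)}, edges as [(id, from, to, radius)]."""
    nodes = {nid: Node(nid, np.asarray(p, dtype=float))
             for nid, p in node_positions.items()}
    edges = {eid: Edge(eid, a, b, r) for eid, a, b, r in edge_specs}
    return VascularTree(nodes, edges, root)


@pytest.fixture(scope="session")
def perfect_depth2():
    return make_perfect_tree(2)


@pytest.fixture(scope="session")
def small_population():
    """Six i.i.d. synthetic trees (25-45 leaves) reused across tests."""
    spec = SyntheticPopulationSpec(n_trees=6, leaf_range=(25, 45), seed=101)
    return make_population(spec)


@pytest.fixture
def one_bifurcation_tree():
    """Root edge into a symmetric planar bifurcation."""
    return build_tree(
        {"r": (0, 0, 0), "a": (0, 0, -10), "b": (5, 0, -15), "c": (-5, 0, -15)},
        [("e0", "r", "a", 1.0), ("e1", "a", "b", 0.5), ("e2", "a", "c", 0.5)],
        "r",
    )
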