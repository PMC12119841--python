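import numpy as np
import pytest

from speciogeo.simulate import GridSpec, simulate_bd_tree
from speciogeo.trees import parse_newick


@pytest.fixture
def two_tip():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def balanced_four():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar():
    return parse_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def small_grid():
    return GridSpec(lat_min=-10, lat_max=10, lon_min=0, lon_max=20,
                    resolution=2.0)


@pytest.fixture
def yule_tree():
    return simulate_bd_tree(0.2, 0.0, 40, seed=42)


def brute_force_dr(newick: str) -> dict[str, float]:
    """Independent inverse equal-splits oracle.

    Explicitly enumerates each leaf's root-to-tip path on a dendropy tree
    (a different data structure from the package's array representation)
    and sums edge lengths with weights halved — 1/m at polytomies — at
    every node crossed rootward.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = {}
    for leaf in tree.leaf_node_iter():
        w = 1.0
        es = 0.0
        node = leaf
        while node.parent_node is not None:
            es += w * node.edge.length
            node = node.parent_node
            w /= len(node.child_nodes())
        out[leaf.taxon.label] = 1.0 / es
    return out
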