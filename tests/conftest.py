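import numpy as np
import pytest

import phyloshift as ps

# four-tip tree with hand-computable path lengths, used across modules:
# PD of all tips = 6.5; d(A,B)=2, d(C,D)=3, d(A,C)=4
TOY_NEWICK = "((A:1,B:1):1,(C:1.5,D:1.5):0.5);"


@pytest.fixture(scope="session")
def toy_tree() -> ps.PhyloTree:
    return ps.PhyloTree.from_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def toy_dist(toy_tree) -> ps.PatristicMatrix:
    return ps.patristic_matrix(toy_tree)


@pytest.fixture(scope="session")
def yule64() -> ps.PhyloTree:
    return ps.simulate_tree(64, seed=11)


@pytest.fixture(scope="session")
def yule64_dist(yule64) -> ps.PatristicMatrix:
    return ps.patristic_matrix(yule64)


@pytest.fixture(scope="session")
def small_scenario() -> ps.Scenario:
    """A small random-shift scenario for fast end-to-end checks."""
    cfg = ps.ScenarioConfig(
        n_species=32, lat_min=40.0, lat_max=48.0, lon_min=0.0, lon_max=8.0, seed=5
    )
    return ps.simulate_scenario(cfg)


def brute_force_pd(tree: ps.PhyloTree, species) -> float:
    """Independent Faith PD oracle: walk each tip's root path on the raw
    dendropy tree and sum the lengths of the union of visited edges."""
    species = set(species)
    dtree = tree.dendropy_tree
    edges: dict[int, float] = {}
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon.label not in species:
            continue
        node = leaf
        while node.parent_node is not None:
            edges[id(node)] = node.edge.length
            node = node.parent_node
    return float(sum(edges.values()))


def brute_force_mpd(dist: ps.PatristicMatrix, species) -> float:
    """Independent MPD oracle: explicit double loop over unordered pairs."""
    sp = sorted(species)
    total, n_pairs = 0.0, 0
    for i in range(len(sp)):
        for j in range(i + 1, len(sp)):
            total += dist.distance(sp[i], sp[j])
            n_pairs += 1
    return total / n_pairs
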