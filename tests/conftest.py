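import numpy as np
import pytest

from fosmap import AnimalDesign, AtlasNode, AtlasTree


@pytest.fixture
def chain_tree() -> AtlasTree:
    """root -> A -> B."""
    return AtlasTree(
        [
            AtlasNode("root", "root", "root", None, 100),
            AtlasNode("A", "A", "A", "root", 50),
            AtlasNode("B", "B", "B", "A", 10),
        ]
    )


@pytest.fixture
def small_design() -> list[AnimalDesign]:
    """24 animals: 3 pairs (2 mate + 1 sibling) at each of 4 timepoints."""
    rows = []
    for t in (1, 2, 3, 4):
        for m in range(2):
            pid = f"t{t}m{m}"
            rows.append(AnimalDesign(f"{pid}F", "F", "mate", t, m + 1, pid))
            rows.append(AnimalDesign(f"{pid}M", "M", "mate", t, m + 1, pid))
        pid = f"t{t}s0"
        sex = "F" if t % 2 == 0 else "M"
        rows.append(AnimalDesign(f"{pid}a", sex, "sibling", t, 3, pid))
        rows.append(AnimalDesign(f"{pid}b", sex, "sibling", t, 3, pid))
    return rows


def random_tree(rng: np.random.Generator, n_nodes: int):
    """Random parent-edge tree over string ids; returns (AtlasTree, edges)."""
    nodes = [AtlasNode("n0", "n0", "node 0", None, int(rng.integers(1, 1000)))]
    edges = {}
    for i in range(1, n_nodes):
        parent = f"n{rng.integers(0, i)}"
        nodes.append(
            AtlasNode(f"n{i}", f"n{i}", f"node {i}", parent, int(rng.integers(1, 1000)))
        )
        edges[f"n{i}"] = parent
    return AtlasTree(nodes), edges
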