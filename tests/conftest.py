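import numpy as np
import pytest

from distimpute import LabeledDistanceMatrix, UnrootedTree

QUARTET_LABELS = ["S1", "S2", "S3", "S4"]
# the five observed distances of the worked quartet example; D13 is missing
QUARTET_OBSERVED = {("S1", "S2"): 2.0, ("S1", "S4"): 5.0, ("S2", "S3"): 3.0,
                    ("S2", "S4"): 5.0, ("S3", "S4"): 4.0}


def quartet_matrix() -> LabeledDistanceMatrix:
    D = np.zeros((4, 4))
    mask = np.zeros((4, 4), dtype=bool)
    idx = {l: i for i, l in enumerate(QUARTET_LABELS)}
    for (a, b), v in QUARTET_OBSERVED.items():
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = v
    mask[idx["S1"], idx["S3"]] = mask[idx["S3"], idx["S1"]] = True
    return LabeledDistanceMatrix(QUARTET_LABELS, D, mask)


@pytest.fixture
def quartet_missing() -> LabeledDistanceMatrix:
    """Five observed distances, D13 masked."""
    return quartet_matrix()


@pytest.fixture
def topology_a() -> UnrootedTree:
    """S1,S2 sisters against S3,S4 (the least-squares optimum)."""
    return UnrootedTree.quartet(("S1", "S2"), ("S3", "S4"))


@pytest.fixture
def topology_b() -> UnrootedTree:
    """S1,S3 sisters: the masked pair are sisters (non-identifiable)."""
    return UnrootedTree.quartet(("S1", "S3"), ("S2", "S4"))


@pytest.fixture
def topology_c() -> UnrootedTree:
    """S1,S4 sisters: exact solve needs a negative internal branch."""
    return UnrootedTree.quartet(("S1", "S4"), ("S2", "S3"))


def terminal_length(tree: UnrootedTree, label: str) -> float:
    """Length of the pendant branch leading to a leaf."""
    nb = tree.neighbors(tree.leaf_node(label))
    (length,) = nb.values()
    return length


def internal_length(tree: UnrootedTree) -> float:
    """Length of the single internal branch of a quartet."""
    (edge,) = tree.internal_branches()
    u, v = tuple(edge)
    return tree.neighbors(u)[v]
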