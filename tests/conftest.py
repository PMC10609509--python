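import numpy as np
import pytest

from slowfast import (
    Alignment,
    discretize_gamma,
    load_model,
    simulate_dataset,
)
from slowfast.phylo import Node, Phylogeny


@pytest.fixture(scope="session")
def lg():
    return load_model("LG")


@pytest.fixture(scope="session")
def cats12():
    return discretize_gamma(0.803, 12)


@pytest.fixture(scope="session")
def medium_sim(lg, cats12):
    """50 taxa x 2000 sites simulated under LG+G12 on a random tree with
    the calibrated branch-length priors; shared by rate-recovery tests."""
    return simulate_dataset(50, 2000, lg, cats12, seed=2024)


def two_taxon_tree(length: float, names=("A", "B")) -> Phylogeny:
    root = Node()
    a = root.add_child(Node(names[0]))
    b = root.add_child(Node(names[1]))
    a.length = length / 2
    b.length = length / 2
    return Phylogeny(root)


@pytest.fixture(scope="session")
def balanced_quartet():
    """((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05) as an unrooted quartet."""
    return Phylogeny.from_newick("((A:0.1,B:0.1):0.05,C:0.1,D:0.1);")
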