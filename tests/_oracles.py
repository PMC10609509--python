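"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: likelihoods by
exhaustive enumeration over internal states, RF by explicit bipartition
sets built from leaf recursion, gamma bin means by numerical quadrature.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from slowfast._aa import MISSING, N_AA
from slowfast.models import RateModel, transition_probabilities
from slowfast.phylo import Node, Phylogeny


def gamma_bin_means_quadrature(alpha: float, k: int) -> np.ndarray:
    """Conditional bin means of a mean-1 gamma by direct numerical
    integration over each equal-probability quantile bin."""
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    bounds[0] = 0.0
    means = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        hi_eff = gamma_dist.ppf(1 - 1e-14, alpha, scale=1.0 / alpha) if np.isinf(hi) else hi
        val, _ = integrate.quad(
            lambda x: x * gamma_dist.pdf(x, alpha, scale=1.0 / alpha), lo, hi_eff,
            limit=200,
        )
        means.append(val * k)
    return np.asarray(means)


def enumerate_site_likelihood(
    tree: Phylogeny, leaf_states: dict[str, int], model: RateModel, rate: float
) -> float:
    """Site likelihood by summing over every internal-state combination."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for combo in itertools.product(range(N_AA), repeat=len(internals)):
        state = dict(zip((id(n) for n in internals), combo))
        prob = model.frequencies[state[id(tree.root)]]
        for node in tree.preorder():
            if node.parent is None:
                continue
            parent_state = state[id(node.parent)]
            P = transition_probabilities(model, node.length, rate)
            if node.is_leaf:
                s = leaf_states[node.name]
                prob_edge = 1.0 if s == MISSING else P[parent_state, s]
            else:
                prob_edge = P[parent_state, state[id(node)]]
            prob *= prob_edge
        total += prob
    return total


def brute_force_splits(tree: Phylogeny) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of taxon labels, built by
    naive leaf collection per edge."""
    all_taxa = frozenset(tree.taxa)
    smallest = min(all_taxa)

    def leaves_below(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        return frozenset().union(*(leaves_below(c) for c in node.children))

    splits = set()
    for node in tree.postorder():
        if node.parent is None:
            continue
        below = leaves_below(node)
        if len(below) < 2 or len(below) > len(all_taxa) - 2:
            continue
        side = below if smallest in below else all_taxa - below
        splits.add(side)
    return splits


def random_binary_tree(n_leaves: int, rng: np.random.Generator, max_len=0.5) -> Phylogeny:
    """Random topology by naive repeated pair-joining (independent of the
    package's random_topology), with random branch lengths."""
    nodes = [Node(f"L{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.01, max_len))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0.01, max_len)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for node in nodes:
        root.add_child(node)
    return Phylogeny(root)


def tree_path_distances(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Exact leaf-to-leaf path-length matrix (additive distances)."""
    taxa = tree.taxa
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    D = np.zeros((n, n))
    below: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.name: 0.0}
        else:
            merged: dict[str, float] = {}
            child_maps = []
            for child in node.children:
                cm = {t: d + (child.length or 0.0) for t, d in below[id(child)].items()}
                child_maps.append(cm)
                merged.update(cm)
            for a, b in itertools.combinations(range(len(child_maps)), 2):
                for ta, da in child_maps[a].items():
                    for tb, db in child_maps[b].items():
                        D[index[ta], index[tb]] = D[index[tb], index[ta]] = da + db
            below[id(node)] = merged
    return taxa, D
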