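import numpy as np
import pandas as pd
import pytest
import dendropy
from dendropy.calculate import treecompare

from slowfast.compare import (
    Bipartition,
    bh_qvalues,
    bipartitions,
    compatible_reference_bipartitions,
    mds_embedding,
    pooled_rate_branchlength_spearman,
    recovery_statistics,
    rf_distance,
    rf_matrix,
    rf_slope,
    spearman,
    support_frequencies,
)
from slowfast.infer import BootstrapSample
from slowfast.phylo import Phylogeny
from slowfast.simulate import random_topology
from _oracles import brute_force_splits, random_binary_tree


def test_bipartitions_basics():
    quartet = Phylogeny.from_newick("((A,B),(C,D));")
    splits = bipartitions(quartet)
    assert splits == {Bipartition(frozenset({"A", "B"}))}
    big = random_topology(1000, seed=2)
    assert len(bipartitions(big)) == 997
    poly = Phylogeny.from_newick("((A,B),C,D,E);")
    assert len(bipartitions(poly)) == 1  # the single resolved edge


def test_rf_distance_basics():
    t1 = Phylogeny.from_newick("((A,B),(C,D));")
    t2 = Phylogeny.from_newick("((A,C),(B,D));")
    assert rf_distance(t1, t1.copy()) == 0
    assert rf_distance(t1, t2) == 2
    assert rf_distance(t1, t2, normalized=True) == pytest.approx(1.0)
    t3 = Phylogeny.from_newick("((A,B),(C,E));")
    with pytest.raises(ValueError, match="leaf sets"):
        rf_distance(t1, t3)


@pytest.mark.parametrize("seed", range(6))
def test_rf_matches_brute_force_and_dendropy(seed):
    """RF equals both the naive bipartition-set oracle and dendropy's
    implementation on random 8-leaf tree pairs."""
    rng = np.random.default_rng(seed)
    t1 = random_binary_tree(8, rng)
    t2 = random_binary_tree(8, rng)
    got = rf_distance(t1, t2)
    oracle = len(brute_force_splits(t1) ^ brute_force_splits(t2))
    assert got == oracle
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    assert got == treecompare.symmetric_difference(d1, d2)


def test_rf_is_a_metric():
    rng = np.random.default_rng(99)
    trees = [random_binary_tree(9, rng) for _ in range(5)]
    for i, a in enumerate(trees):
        assert rf_distance(a, a.copy()) == 0
        for b in trees[i + 1:]:
            assert rf_distance(a, b) == rf_distance(b, a)
            for c in trees:
                assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


def test_support_frequencies():
    base = Phylogeny.from_newick("((A,B),(C,D),E);")
    other = Phylogeny.from_newick("((A,C),(B,D),E);")
    sample = BootstrapSample([base.copy() for _ in range(8)] + [other, other.copy()], 10)
    freqs = support_frequencies(sample)
    ab = Bipartition(frozenset({"A", "B"}))
    assert freqs[ab] == pytest.approx(0.8)
    # double-counting identity: sum over splits of freq*n equals total splits
    total = sum(f * 10 for f in freqs.values())
    assert total == sum(len(t.split_masks()) for t in sample.trees)


def test_compatible_reference_bipartitions():
    ref = Phylogeny.from_newick("((A:1,B:1):0.5,(C:1,D:1):0.5,E:1);")
    perfect = BootstrapSample([ref.copy() for _ in range(10)], 10)
    table = compatible_reference_bipartitions(ref, perfect)
    assert table["recovered"].all()
    assert table.shape[0] == 2
    deviant = Phylogeny.from_newick("((A:1,C:1):0.5,(B:1,D:1):0.5,E:1);")
    mixed = BootstrapSample([ref.copy() for _ in range(9)] + [deviant], 10)
    strict = compatible_reference_bipartitions(ref, mixed, threshold=1.0)
    assert not strict["recovered"].any()
    loose = compatible_reference_bipartitions(ref, mixed, threshold=0.8)
    assert loose["recovered"].all()


def _toy_table():
    """Two partitions x four reference splits with branch lengths 1..4:
    partition A recovers only the two longest, partition B recovers all."""
    rows = []
    for pid, rate, recovered_set in [("A", 0.1, {3, 4}), ("B", 2.0, {1, 2, 3, 4})]:
        for bl in (1, 2, 3, 4):
            rows.append(
                {
                    "partition": pid,
                    "mean_rate": rate,
                    "bipartition": f"s{bl}",
                    "branch_length": float(bl),
                    "support": 1.0 if bl in recovered_set else 0.0,
                    "recovered": bl in recovered_set,
                }
            )
    # a third partition so the statistics have >= 3 groups
    for bl in (1, 2, 3, 4):
        rows.append(
            {
                "partition": "C",
                "mean_rate": 1.0,
                "bipartition": f"s{bl}",
                "branch_length": float(bl),
                "support": 1.0 if bl >= 2 else 0.0,
                "recovered": bl >= 2,
            }
        )
    return pd.DataFrame(rows)


def test_recovery_statistics_hand_built():
    stats = recovery_statistics(_toy_table())
    per = stats["per_partition"].set_index("partition")
    # reference median branch length is 2.5; below-median splits are 1 and 2
    assert per.loc["A", "below_median_recovery"] == 0.0
    assert per.loc["B", "below_median_recovery"] == 1.0
    assert per.loc["A", "top_quartile_recovery"] == 1.0
    assert stats["reference_median_branch_length"] == pytest.approx(2.5)
    rho, p = pooled_rate_branchlength_spearman(_toy_table())
    assert rho < 0  # the faster partition recovers shorter branches


def test_recovery_statistics_degenerate():
    table = _toy_table()
    table["recovered"] = True
    table["support"] = 1.0
    stats = recovery_statistics(table)
    assert np.isnan(stats["spearman_rho"])  # constant medians -> undefined
    assert (stats["per_partition"]["below_median_recovery"] == 1.0).all()


def test_spearman_exact_small_n():
    rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 120)  # only the two monotone permutations
    x = np.arange(12)
    y = x + np.random.default_rng(0).normal(0, 3, 12)
    from scipy.stats import spearmanr
    rho2, p2 = spearman(x, y)
    ref = spearmanr(x, y)
    assert rho2 == pytest.approx(ref.statistic)
    assert p2 == pytest.approx(ref.pvalue)


def test_bh_qvalues_monotone():
    p = np.array([0.001, 0.02, 0.04, 0.3, 0.9])
    q = bh_qvalues(p)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
    assert np.all(q <= 1) and np.all(q >= p - 1e-12)


def test_rf_slope():
    assert rf_slope({9: [5, 5], 10: [5], 11: [5, 5, 5], 12: [5]}, np.ones(12)* np.arange(1, 13)) == pytest.approx(0.0)
    assert rf_slope({1: [10], 2: [20]}, [1, 2] + [0] * 10, category_range=(1, 2)) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        rf_slope({9: [1]}, np.arange(1, 13), category_range=(9, 9))


def test_mds_embedding():
    # 3-4-5 right triangle embeds exactly
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    X = mds_embedding(D)
    got = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    np.testing.assert_allclose(got, D, atol=1e-9)
    # duplicated point lands on its twin
    D2 = np.array(
        [[0, 0, 4], [0, 0, 4], [4, 4, 0]], dtype=float
    )
    X2 = mds_embedding(D2)
    np.testing.assert_allclose(X2[0], X2[1], atol=1e-6)
    # eigen-truncation never stretches Euclidean-embeddable metrics
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(7, 5))
    D3 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    X3 = mds_embedding(D3)
    emb = np.sqrt(((X3[:, None] - X3[None, :]) ** 2).sum(-1))
    assert np.all(emb <= D3 + 1e-9)
    # determinism up to the fixed sign convention
    np.testing.assert_allclose(mds_embedding(D3), X3)


def test_rf_matrix_consistency():
    rng = np.random.default_rng(1)
    trees = [random_binary_tree(7, rng) for _ in range(4)]
    M = rf_matrix(trees)
    for i in range(4):
        for j in range(4):
            assert M[i, j] == rf_distance(trees[i], trees[j])
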