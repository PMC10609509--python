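import numpy as np
import pytest

from slowfast import Alignment, discretize_gamma, simulate_dataset
from slowfast._aa import AA_ORDER, decode
from slowfast.infer import (
    BootstrapSample,
    DistanceMatrix,
    PairwiseEngine,
    UndefinedDistanceError,
    bootstrap_trees,
    empirical_frequencies,
    estimate_tree,
    ml_pairwise_distance,
    nni_refine,
    nj_tree,
    pairwise_distance_matrix,
    score_model,
    select_best_model,
    subsample_branch_profile,
)
from slowfast.models import load_model
from slowfast.simulate import (
    assign_branch_lengths,
    evolve_alignment,
    random_topology,
)
from conftest import two_taxon_tree
from _oracles import random_binary_tree, tree_path_distances


# ---------------------------------------------------------------------------
# pairwise ML distances
# ---------------------------------------------------------------------------

def test_identical_sequences_distance_zero(lg, cats12):
    d, sat = ml_pairwise_distance("ARNDCQ", "ARNDCQ", lg, cats12)
    assert d == 0.0 and not sat
    # gapped sites are skipped
    d, sat = ml_pairwise_distance("AR-DCQ", "ARND-Q", lg, cats12)
    assert d == 0.0 and not sat
    with pytest.raises(UndefinedDistanceError):
        ml_pairwise_distance("A---", "-RND", lg, cats12)


def test_distance_round_trip(lg, cats12):
    """ML distance recovers the generating branch length on a 2-taxon tree
    (5000 sites; Monte-Carlo tolerance)."""
    res = evolve_alignment(two_taxon_tree(0.3), lg, cats12, 5000, seed=21)
    a, b = res.alignment.data
    d, sat = ml_pairwise_distance(a, b, lg, cats12)
    assert not sat
    assert d == pytest.approx(0.3, abs=0.04)


def test_saturated_pair_capped(lg, cats12):
    """Two sequences differing at every site drive the estimate to the cap."""
    a = (AA_ORDER * 40)[:800]
    b = (AA_ORDER[1:] + AA_ORDER[0])
    b = (b * 40)[:800]
    d, sat = ml_pairwise_distance(a, b, lg, cats12, max_distance=10.0)
    assert sat and d == 10.0


def test_engine_matches_single_pair_estimator(lg, cats12):
    """The shared-grid engine agrees with the bounded-search estimator."""
    sim = simulate_dataset(8, 1500, lg, cats12, seed=33)
    eng = PairwiseEngine(sim.alignment, lg, cats12)
    D = eng.distances()
    for (i, j) in [(0, 1), (2, 5), (3, 7)]:
        exact, sat = ml_pairwise_distance(
            sim.alignment.data[i], sim.alignment.data[j], lg, cats12
        )
        if not sat:
            assert D.values[i, j] == pytest.approx(exact, rel=0.02, abs=0.005)


def test_distance_estimator_consistency(lg, cats12):
    """Bias shrinks as the alignment grows (three lengths)."""
    biases = []
    for n_sites in (500, 4000, 32000):
        res = evolve_alignment(two_taxon_tree(0.4), lg, cats12, n_sites, seed=55)
        d, _ = ml_pairwise_distance(*res.alignment.data, lg, cats12)
        biases.append(abs(d - 0.4))
    assert biases[2] < biases[0]
    assert biases[2] < 0.02


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_exact_on_additive_distances():
    """NJ reconstructs the generating topology and branch lengths from an
    exactly additive matrix."""
    rng = np.random.default_rng(7)
    source = random_binary_tree(5, rng)
    taxa, D = tree_path_distances(source)
    tree = nj_tree(DistanceMatrix(taxa, D))
    assert set(tree.split_masks()) == set(source.split_masks())
    got = dict(tree.split_masks())
    want = dict(source.split_masks())
    for mask, ln in want.items():
        assert got[mask] == pytest.approx(ln, abs=1e-9)
    # leaf branch lengths too
    leaf_len_got = {n.name: n.length for n in tree.leaves()}
    leaf_len_want = {n.name: n.length for n in source.leaves()}
    for t in taxa:
        assert leaf_len_got[t] == pytest.approx(leaf_len_want[t], abs=1e-9)


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
    lengths = {n.name: n.length for n in tree.leaves()}
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def test_nj_label_order_invariance():
    rng = np.random.default_rng(11)
    source = random_binary_tree(7, rng)
    taxa, D = tree_path_distances(source)
    perm = rng.permutation(len(taxa))
    shuffled = nj_tree(DistanceMatrix([taxa[i] for i in perm], D[np.ix_(perm, perm)]))
    assert set(shuffled.split_masks()) == set(source.split_masks())
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    bad = np.array([[0, np.inf], [np.inf, 0]])
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)) + np.diag([0, 0, 0])))
        nj_tree(DistanceMatrix(["a", "b"], bad))


def test_nni_refine_preserves_additive_optimum():
    """Balanced-NNI hill climbing leaves the exact NJ solution of an
    additive matrix untouched (it is already the minimum-evolution tree)."""
    rng = np.random.default_rng(23)
    source = random_binary_tree(10, rng)
    taxa, D = tree_path_distances(source)
    d = DistanceMatrix(taxa, D)
    nj = nj_tree(d)
    refined = nni_refine(nj, d)
    assert set(refined.split_masks()) == set(source.split_masks())
    assert sorted(l.name for l in refined.leaves()) == sorted(taxa)


def test_nni_refine_improves_noisy_topology(lg, cats12):
    """On noisy simulated distances the refinement never loses accuracy on
    average and typically improves it."""
    sim = simulate_dataset(40, 600, lg, cats12, seed=91)
    d = pairwise_distance_matrix(sim.alignment, lg, cats12)
    nj = nj_tree(d)
    refined = nni_refine(nj, d)
    true_splits = set(sim.tree.split_masks())
    rf_nj = len(set(nj.split_masks()) ^ true_splits)
    rf_ref = len(set(refined.split_masks()) ^ true_splits)
    assert rf_ref <= rf_nj


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_determinism_and_degeneracy(lg, cats12):
    sim = simulate_dataset(6, 300, lg, cats12, seed=3)
    one = bootstrap_trees(sim.alignment, 1, lg, cats12, seed=99)
    two = bootstrap_trees(sim.alignment, 1, lg, cats12, seed=99)
    assert one.trees[0].to_newick() == two.trees[0].to_newick()
    # constant-column alignment: every replicate equals the point estimate
    col = sim.alignment.data[:, :1]
    constant = Alignment(sim.alignment.taxa, np.repeat(col, 50, axis=1))
    sample = bootstrap_trees(constant, 5, lg, cats12, seed=1)
    point = estimate_tree(constant, lg, cats12)
    for t in sample.trees:
        assert set(t.split_masks()) == set(point.split_masks())
    with pytest.raises(ValueError):
        bootstrap_trees(Alignment(["a", "b"], col[:2]), 2, lg, cats12, seed=0)


def test_bootstrap_recovers_strong_signal(lg, cats12):
    """With every branch at 0.3 substitutions/site, essentially all
    replicates recover every true bipartition."""
    tree = random_topology(50, seed=8)
    for node in tree.edges():
        node.length = 0.3
    res = evolve_alignment(tree, lg, cats12, 2000, seed=9)
    sample = bootstrap_trees(res.alignment, 40, lg, cats12, seed=10)
    true_masks = set(tree.split_masks())
    for mask in true_masks:
        support = sum(mask in t.split_masks() for t in sample.trees) / 40
        assert support >= 0.95


def test_bootstrap_sample_io(tmp_path, lg, cats12):
    sim = simulate_dataset(6, 200, lg, cats12, seed=4)
    sample = bootstrap_trees(sim.alignment, 3, lg, cats12, seed=5)
    path = tmp_path / "sample.nwk"
    sample.write(path)
    loaded = BootstrapSample.read(path)
    assert loaded.n_replicates == 3
    for a, b in zip(sample.trees, loaded.trees):
        assert set(a.split_masks()) == set(b.split_masks())


# ---------------------------------------------------------------------------
# model scoring
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("true_model", ["LG", "Dayhoff"])
def test_model_recovery(true_model, cats12):
    """Fixed-tree BIC selection recovers the generating model family."""
    gen = load_model(true_model)
    sim = simulate_dataset(30, 3000, gen, discretize_gamma(0.803, 1), seed=12)
    candidates = [load_model(m) for m in ("LG", "WAG", "Dayhoff", "JTT")]
    table = select_best_model(sim.alignment, sim.tree, candidates)
    assert table.shape[0] == 8
    best = table.iloc[0]
    assert best["model"].startswith(true_model)
    assert not best["empirical_freqs"]  # default frequencies generated the data


def test_empirical_frequency_scoring_is_nested(lg):
    sim = simulate_dataset(10, 500, lg, discretize_gamma(0.803, 1), seed=13)
    plain = score_model(sim.alignment, sim.tree, lg, use_empirical_freqs=False)
    emp = score_model(sim.alignment, sim.tree, lg, use_empirical_freqs=True)
    assert plain.n_parameters == 0 and emp.n_parameters == 19
    assert emp.bic == pytest.approx(
        -2 * emp.log_likelihood + 19 * np.log(sim.alignment.n_sites)
    )
    freqs = empirical_frequencies(sim.alignment)
    assert freqs.sum() == pytest.approx(1.0)
    # refitting with the model's own frequencies changes nothing but the BIC
    refit = lg.with_frequencies(lg.frequencies)
    np.testing.assert_allclose(refit.generator, lg.generator, atol=1e-12)


# ---------------------------------------------------------------------------
# taxon subsampling
# ---------------------------------------------------------------------------

def test_subsample_branch_profile(lg, cats12):
    sim = simulate_dataset(40, 400, lg, cats12, seed=14)
    prof = subsample_branch_profile(
        sim.alignment, sim.tree, [0.3, 0.6, 1.0], n_reps=3, seed=15,
        model=lg, cats=cats12,
    )
    assert list(prof["fraction"]) == [0.3, 0.6, 1.0]
    # the full sample equals the full-data re-estimate
    full_tree = nj_tree(pairwise_distance_matrix(sim.alignment, lg, cats12))
    full_mean = np.mean([e.length or 0.0 for e in full_tree.edges()])
    assert prof["mean_branch_length"].iloc[-1] == pytest.approx(full_mean, rel=1e-4)
    # sparser taxon sampling -> longer average branches
    assert prof["mean_branch_length"].iloc[0] > prof["mean_branch_length"].iloc[-1]
    # determinism
    again = subsample_branch_profile(
        sim.alignment, sim.tree, [0.3, 0.6, 1.0], n_reps=3, seed=15,
        model=lg, cats=cats12,
    )
    assert prof.equals(again)


def test_subsample_restrict_mode_trend(lg, cats12):
    """Pruning the reference tree shows the same downward trend in mean
    branch length as sampling grows."""
    sim = simulate_dataset(80, 100, lg, cats12, seed=16)
    prof = subsample_branch_profile(
        sim.alignment, sim.tree, [0.2, 0.5, 0.8], n_reps=5, seed=17, mode="restrict"
    )
    means = list(prof["mean_branch_length"])
    assert means[0] > means[-1]
    with pytest.warns(UserWarning):
        subsample_branch_profile(
            sim.alignment, sim.tree, [0.01], n_reps=1, seed=1, mode="restrict"
        )
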