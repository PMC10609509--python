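"""Desk-scale tree estimation: maximum-likelihood pairwise distances under a
reversible model with discrete-gamma rates, neighbor joining, nonparametric
bootstrap tree samples, fixed-tree model scoring, and taxon-subsampling
branch-length profiles.

The bootstrap here is the classical nonparametric one: alignment columns are
resampled with replacement and the whole distance + NJ estimation is redone
per replicate, yielding a sample of trees per partition. An adapter is
provided to ingest externally produced multi-tree Newick samples instead.

Pairwise distances maximise the mixture likelihood
``sum_sites log sum_c (1/k) pi_a P_ab(r_c t)`` over the branch length t.
The public single-pair estimator uses a bounded Brent search; the matrix /
bootstrap path shares one precomputed likelihood grid over t (log-spaced,
with parabolic refinement around the grid optimum), which is what makes
thousands of bootstrap replicates tractable on one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._aa import MISSING, N_AA, encode
from .alignment import Alignment
from .models import (
    GammaRateCategories,
    RateModel,
    transition_probability_stack,
)
from .phylo import Node, Phylogeny

DEFAULT_MAX_DISTANCE = 10.0
_N_CODES = (N_AA + 1) ** 2  # pair codes incl. the missing state


class UndefinedDistanceError(ValueError):
    """No shared ungapped sites between two sequences."""


@dataclass
class DistanceMatrix:
    """Symmetric ML distance matrix with saturation bookkeeping."""

    taxa: list[str]
    values: np.ndarray
    saturated_pairs: set = field(default_factory=set)

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12) or np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must be symmetric with a zero diagonal")


@dataclass
class BootstrapSample:
    """A sample of trees estimated from column-resampled alignments."""

    trees: list[Phylogeny]
    n_replicates: int
    source: str = ""
    seed: int = -1
    method: str = "ml-distance+nj"

    def __post_init__(self):
        if len(self.trees) != self.n_replicates:
            raise ValueError("|trees| must equal n_replicates")
        leaf_sets = {frozenset(t.taxa) for t in self.trees}
        if len(leaf_sets) > 1:
            raise ValueError("all bootstrap trees must share one leaf set")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for tree in self.trees:
                fh.write(tree.to_newick() + "\n")

    @classmethod
    def read(cls, path, source: str = "external") -> "BootstrapSample":
        trees = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    trees.append(Phylogeny.from_newick(line))
        return cls(trees=trees, n_replicates=len(trees), source=source, method="external")


# ---------------------------------------------------------------------------
# pairwise ML distances
# ---------------------------------------------------------------------------

def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """20x20 site-pattern counts over shared ungapped sites."""
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        raise UndefinedDistanceError("no shared ungapped sites between the sequences")
    codes = a[ok].astype(np.int64) * N_AA + b[ok]
    return np.bincount(codes, minlength=N_AA * N_AA).reshape(N_AA, N_AA).astype(float)


def _mixture_site_probs(model: RateModel, cats: GammaRateCategories, t: float) -> np.ndarray:
    """pi_a * mean_c P_ab(r_c t): joint probability of the ordered pair."""
    P = transition_probability_stack(model, t, cats.rates).mean(axis=0)
    return model.frequencies[:, None] * P


def ml_pairwise_distance(
    seq_a,
    seq_b,
    model: RateModel,
    cats: GammaRateCategories,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> tuple[float, bool]:
    """ML distance between two aligned sequences under the gamma mixture.

    Returns ``(distance, saturated)``; ``saturated`` is True when the
    optimum sits at the ``max_distance`` cap. Sites where either sequence
    is gapped/ambiguous are skipped.
    """
    a = encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a, dtype=np.uint8)
    b = encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned lengths")
    N = _pair_counts(a, b)
    if np.sum(N) == np.trace(N):  # identical over all comparable sites
        return 0.0, False

    def neg_loglik(t: float) -> float:
        J = _mixture_site_probs(model, cats, t)
        return -float(np.sum(N * np.log(np.maximum(J, 1e-300))))

    res = minimize_scalar(
        neg_loglik,
        bounds=(1e-8, max_distance),
        method="bounded",
        options={"xatol": 1e-8},
    )
    t_hat = float(res.x)
    if t_hat >= max_distance * (1 - 1e-3):
        return max_distance, True
    return t_hat, False


class PairwiseEngine:
    """Shared-grid ML distance engine for all taxon pairs of one alignment.

    Precomputes, once per alignment, (i) the per-pair site code matrix and
    (ii) the mixture log-likelihood of every pair code over a log-spaced
    grid of candidate distances. A bootstrap replicate then only reweights
    site counts, so each replicate's full distance matrix is two matrix
    products plus a parabolic refinement around each pair's grid optimum.
    """

    def __init__(
        self,
        alignment: Alignment,
        model: RateModel,
        cats: GammaRateCategories,
        max_distance: float = DEFAULT_MAX_DISTANCE,
        grid_size: int = 160,
        t_min: float = 5e-4,
    ):
        self.alignment = alignment
        self.model = model
        self.cats = cats
        self.max_distance = float(max_distance)
        n = alignment.n_taxa
        self.pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        data = alignment.data.astype(np.int32)
        ii = np.array([p[0] for p in self.pairs])
        jj = np.array([p[1] for p in self.pairs])
        self._codes = (data[ii] * (N_AA + 1) + data[jj]).astype(np.int16)
        # grid of candidate distances (log-spaced) and per-code log-probs
        self.grid = np.geomspace(t_min, self.max_distance, grid_size)
        logM = np.zeros((_N_CODES, grid_size), dtype=np.float64)
        for g, t in enumerate(self.grid):
            J = _mixture_site_probs(model, cats, t)
            block = np.log(np.maximum(J, 1e-300))
            col = np.zeros((N_AA + 1, N_AA + 1))
            col[:N_AA, :N_AA] = block  # codes touching MISSING contribute 0
            logM[:, g] = col.ravel()
        self._logM = logM.astype(np.float32)
        mismatch = np.zeros(_N_CODES, dtype=np.float32)
        for a in range(N_AA):
            for b in range(N_AA):
                if a != b:
                    mismatch[a * (N_AA + 1) + b] = 1.0
        self._mismatch = mismatch

    def counts(self, weights: np.ndarray | None = None) -> np.ndarray:
        """(n_pairs, n_codes) weighted pair-code counts."""
        n_pairs = len(self.pairs)
        N = np.empty((n_pairs, _N_CODES), dtype=np.float32)
        for p in range(n_pairs):
            N[p] = np.bincount(self._codes[p], weights=weights, minlength=_N_CODES)
        return N

    def distances(self, weights: np.ndarray | None = None) -> DistanceMatrix:
        N = self.counts(weights)
        ll = N @ self._logM  # (n_pairs, grid)
        best = np.argmax(ll, axis=1)
        logt = np.log(self.grid)
        t_hat = np.empty(len(self.pairs))
        # parabolic refinement in log-distance around each grid optimum
        for p, g in enumerate(best):
            if g == 0 or g == len(self.grid) - 1:
                t_hat[p] = self.grid[g]
                continue
            y0, y1, y2 = ll[p, g - 1], ll[p, g], ll[p, g + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.0 if denom >= 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            t_hat[p] = np.exp(logt[g] + shift * (logt[g + 1] - logt[g]))
        n_mismatch = N @ self._mismatch
        t_hat[n_mismatch == 0] = 0.0
        saturated = best == len(self.grid) - 1
        n = self.alignment.n_taxa
        D = np.zeros((n, n))
        sat_pairs = set()
        for p, (i, j) in enumerate(self.pairs):
            D[i, j] = D[j, i] = t_hat[p]
            if saturated[p] and t_hat[p] > 0:
                sat_pairs.add((self.alignment.taxa[i], self.alignment.taxa[j]))
        return DistanceMatrix(list(self.alignment.taxa), D, sat_pairs)


def pairwise_distance_matrix(
    alignment: Alignment,
    model: RateModel,
    cats: GammaRateCategories,
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> DistanceMatrix:
    """ML distance matrix for every taxon pair (shared-grid engine)."""
    return PairwiseEngine(alignment, model, cats, max_distance).distances()


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> Phylogeny:
    """Standard neighbor joining; deterministic lowest-index tie-break,
    negative branch-length estimates clamped to zero."""
    D = np.array(d.values, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances in input matrix")
    m = len(d.taxa)
    if m < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {m}")
    nodes: list[Node] = [Node(name) for name in d.taxa]
    while m > 3:
        rowsum = D.sum(axis=1)
        Q = (m - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum: lowest (i, j) row-major
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = Node()
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        # replace slot i with the merged node, drop slot j
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [x for x in range(m) if x != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
        m -= 1
    # resolve the final 3-star with closed-form lengths
    root = Node()
    l0 = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    l1 = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    l2 = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(0.0, ln)
        root.add_child(node)
    return Phylogeny(root)


def nni_refine(tree: Phylogeny, d: DistanceMatrix, max_sweeps: int = 20) -> Phylogeny:
    """Balanced nearest-neighbour-interchange hill climbing on the NJ tree.

    Every internal edge partitions the leaves into four subtrees A, B | C, D.
    Using *balanced* subtree averages (each bifurcation weighs its two sides
    1/2 regardless of size, the Desper-Gascuel balanced minimum-evolution
    convention), the quartet pairing with the smallest
    ``avg(A,B) + avg(C,D)`` is kept; sweeps repeat until no interchange
    improves it. Topology only: branch lengths are not refit here.
    """
    tree = tree.copy()
    index = {t: i for i, t in enumerate(d.taxa)}
    D = d.values
    n = len(d.taxa)

    def balanced_weights():
        """Per-node leaf-weight vectors, for the subtree below each node
        (down) and the complement subtree above it (up)."""
        down: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                w = np.zeros(n)
                w[index[node.name]] = 1.0
            else:
                w = np.mean([down[c] for c in node.children], axis=0)
            down[node] = w
        up: dict[Node, np.ndarray] = {}
        for node in tree.preorder():
            if node.parent is None:
                continue
            siblings = [c for c in node.parent.children if c is not node]
            parts = [down[s] for s in siblings]
            if node.parent.parent is not None:
                parts.append(up[node.parent])
            up[node] = np.mean(parts, axis=0)
        return down, up

    for _ in range(max_sweeps):
        improved = False
        # weights refresh once per sweep; later edges in a sweep see mildly
        # stale averages, which the next sweep corrects
        down, up = balanced_weights()
        Dd = {node: D @ w for node, w in down.items()}
        Du = {node: D @ w for node, w in up.items()}
        for v in list(tree.postorder()):
            u = v.parent
            if u is None or v.is_leaf or len(v.children) != 2:
                continue
            if v not in down or u not in down:
                continue  # structure changed earlier in this sweep
            siblings = [c for c in u.children if c is not v]
            if len(siblings) == 1 and u.parent is not None:
                c_node = siblings[0]
                DwR = Du[u]
            elif len(siblings) == 2 and u.parent is None:
                c_node = siblings[0]
                DwR = Dd[siblings[1]]
            else:
                continue
            a_node, b_node = v.children
            if a_node not in down or b_node not in down or c_node not in down:
                continue
            wA, wB, wC = down[a_node], down[b_node], down[c_node]
            current = wA @ Dd[b_node] + wC @ DwR
            swap_bc = wA @ Dd[c_node] + wB @ DwR
            swap_ac = wC @ Dd[b_node] + wA @ DwR
            best = min(swap_bc, swap_ac)
            if best >= current - 1e-12:
                continue
            inner = b_node if swap_bc <= swap_ac else a_node
            v.children[v.children.index(inner)] = c_node
            u.children[u.children.index(c_node)] = inner
            c_node.parent, inner.parent = v, u
            improved = True
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def estimate_tree(
    alignment: Alignment,
    model: RateModel,
    cats: GammaRateCategories,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    refine: bool = True,
) -> Phylogeny:
    """Point estimate: ML distances -> NJ -> balanced-NNI refinement."""
    d = pairwise_distance_matrix(alignment, model, cats, max_distance)
    tree = nj_tree(d)
    return nni_refine(tree, d) if refine else tree


def bootstrap_trees(
    alignment: Alignment,
    n_replicates: int,
    model: RateModel,
    cats: GammaRateCategories,
    seed,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    source: str = "",
    engine: PairwiseEngine | None = None,
    refine: bool = True,
) -> BootstrapSample:
    """Classical nonparametric bootstrap: resample columns with replacement,
    re-estimate ML distances and the NJ (+ balanced-NNI) tree for every
    replicate."""
    if alignment.n_taxa < 4:
        raise ValueError("need at least 4 taxa to bootstrap trees")
    if alignment.n_sites < 1:
        raise ValueError("need at least 1 site")
    rng = np.random.default_rng(seed)
    engine = engine or PairwiseEngine(alignment, model, cats, max_distance)
    n_sites = alignment.n_sites
    trees = []
    for r in range(n_replicates):
        weights = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites)).astype(
            np.float64
        )
        try:
            d = engine.distances(weights)
            tree = nj_tree(d)
            if refine:
                tree = nni_refine(tree, d)
            trees.append(tree)
        except Exception as exc:  # annotate with the replicate index
            raise RuntimeError(f"bootstrap replicate {r} failed: {exc}") from exc
    return BootstrapSample(
        trees=trees,
        n_replicates=n_replicates,
        source=source,
        seed=int(seed) if isinstance(seed, (np.integer,)) or isinstance(seed, int) else -1,
    )


# ---------------------------------------------------------------------------
# fixed-tree model scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelScore:
    model: str
    empirical_freqs: bool
    log_likelihood: float
    n_parameters: int
    bic: float


def empirical_frequencies(alignment: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Observed residue frequencies over non-gap cells (light pseudocount so
    unobserved residues keep a proper, reversible generator)."""
    counts = np.bincount(alignment.data[alignment.data != MISSING], minlength=N_AA)
    counts = counts.astype(float) + pseudocount
    return counts / counts.sum()


def score_model(
    alignment: Alignment,
    tree: Phylogeny,
    model: RateModel,
    use_empirical_freqs: bool = False,
) -> ModelScore:
    """Total pruning log-likelihood on a fixed tree at a homogeneous rate,
    and its BIC (empirical +F frequencies add 19 free parameters)."""
    from .siterates import site_category_log_likelihoods

    fitted = (
        model.with_frequencies(empirical_frequencies(alignment))
        if use_empirical_freqs
        else model
    )
    ll = float(
        site_category_log_likelihoods(alignment, tree, fitted, np.array([1.0])).sum()
    )
    p = 19 if use_empirical_freqs else 0
    bic = -2.0 * ll + p * np.log(alignment.n_sites)
    return ModelScore(
        model=fitted.name,
        empirical_freqs=use_empirical_freqs,
        log_likelihood=ll,
        n_parameters=p,
        bic=float(bic),
    )


def select_best_model(
    alignment: Alignment,
    tree: Phylogeny,
    models: list[RateModel],
) -> pd.DataFrame:
    """Score every (model, default/empirical frequency) combination on a
    fixed tree; rows sorted by BIC, best first."""
    rows = []
    for model in models:
        for emp in (False, True):
            s = score_model(alignment, tree, model, use_empirical_freqs=emp)
            rows.append(
                {
                    "model": s.model,
                    "empirical_freqs": s.empirical_freqs,
                    "log_likelihood": s.log_likelihood,
                    "n_parameters": s.n_parameters,
                    "bic": s.bic,
                }
            )
    return pd.DataFrame(rows).sort_values("bic", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# taxon subsampling
# ---------------------------------------------------------------------------

def subsample_branch_profile(
    alignment: Alignment,
    reference: Phylogeny,
    fractions,
    n_reps: int,
    seed,
    model: RateModel | None = None,
    cats: GammaRateCategories | None = None,
    mode: str = "reinfer",
    max_distance: float = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Mean branch length of trees re-estimated from random taxon subsamples.

    For each fraction, ``n_reps`` subsamples of the reference leaf set are
    drawn without replacement; ``mode='reinfer'`` re-estimates the tree on
    the restricted alignment (ML distances + NJ), ``mode='restrict'`` prunes
    the reference tree to the subsample and keeps its branch lengths.
    Subsamples below 4 taxa are skipped with a warning.
    """
    if mode not in ("reinfer", "restrict"):
        raise ValueError("mode must be 'reinfer' or 'restrict'")
    rng = np.random.default_rng(seed)
    taxa = reference.taxa
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fractions must lie in (0, 1], got {frac}")
        n_sub = int(round(frac * len(taxa)))
        if n_sub < 4:
            warnings.warn(f"fraction {frac}: subsample of {n_sub} taxa skipped (< 4)")
            continue
        means = []
        for _ in range(n_reps):
            chosen = sorted(rng.choice(taxa, size=n_sub, replace=False))
            if mode == "reinfer":
                sub = alignment.select_taxa(chosen)
                tree = nj_tree(
                    pairwise_distance_matrix(sub, model, cats, max_distance)
                )
            else:
                tree = _prune_to(reference, set(chosen))
            lengths = [e.length or 0.0 for e in tree.edges()]
            means.append(float(np.mean(lengths)))
        rows.append(
            {
                "fraction": float(frac),
                "n_taxa": n_sub,
                "mean_branch_length": float(np.mean(means)),
                "sd_branch_length": float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _prune_to(tree: Phylogeny, keep: set) -> Phylogeny:
    """Induced subtree on a leaf subset; suppressed unifurcations merge
    branch lengths additively."""
    work = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.name in keep else None
        kept = [c for c in (prune(ch) for ch in list(node.children)) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            child.parent = None
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    new_root = prune(work.root)
    if new_root is None:
        raise ValueError("pruning removed every leaf")
    return Phylogeny(new_root)
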