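"""Bipartition statistics: Robinson-Foulds distances, bootstrap support,
recovery of reference bipartitions by rate partition, rate-vs-branch-length
correlations with FDR control, regression slopes, and classical MDS of tree
space.

A bipartition (split) is the pair of leaf sets induced by removing an
internal edge of an unrooted tree; it is stored canonically as the side
containing the lexicographically smallest taxon label. A reference
bipartition counts as *recovered* ("compatible") by a bootstrap sample when
it appears in at least a threshold fraction (default 80%) of the sampled
trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .infer import BootstrapSample
from .phylo import Phylogeny

DEFAULT_RECOVERY_THRESHOLD = 0.8


@dataclass(frozen=True)
class Bipartition:
    """Canonical split: the side holding the smallest taxon label."""

    side: frozenset

    def __post_init__(self):
        if len(self.side) < 2:
            raise ValueError("bipartition sides must contain at least 2 taxa")

    @classmethod
    def from_mask(cls, mask: int, taxa: list[str]) -> "Bipartition":
        side = frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)
        return cls(side)

    def __str__(self) -> str:
        return "|".join(sorted(self.side))


def bipartitions(tree: Phylogeny, with_lengths: bool = False):
    """Canonical non-trivial bipartitions of a tree (one per internal
    edge); optionally a dict to branch lengths."""
    taxa = tree.taxa
    masks = tree.split_masks()
    if with_lengths:
        return {Bipartition.from_mask(m, taxa): ln for m, ln in masks.items()}
    return {Bipartition.from_mask(m, taxa) for m in masks}


def _check_same_taxa(t1: Phylogeny, t2: Phylogeny) -> None:
    a, b = set(t1.taxa), set(t2.taxa)
    if a != b:
        raise ValueError(
            f"trees have different leaf sets; only in first: {sorted(a - b)}, "
            f"only in second: {sorted(b - a)}"
        )


def rf_distance(t1: Phylogeny, t2: Phylogeny, normalized: bool = False) -> float:
    """Robinson-Foulds distance: size of the symmetric difference of the two
    bipartition sets (normalised variant divides by |B1| + |B2|)."""
    _check_same_taxa(t1, t2)
    b1 = set(t1.split_masks())
    b2 = set(t2.split_masks())
    rf = len(b1 ^ b2)
    if normalized:
        total = len(b1) + len(b2)
        return rf / total if total else 0.0
    return rf


def rf_matrix(trees: list[Phylogeny], normalized: bool = False) -> np.ndarray:
    """Pairwise RF distances among a list of trees sharing one leaf set."""
    splits = [set(t.split_masks()) for t in trees]
    n = len(trees)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rf = len(splits[i] ^ splits[j])
            if normalized:
                total = len(splits[i]) + len(splits[j])
                rf = rf / total if total else 0.0
            D[i, j] = D[j, i] = rf
    return D


def support_frequencies(sample: BootstrapSample) -> dict[Bipartition, float]:
    """Fraction of sampled trees containing each observed bipartition."""
    if sample.n_replicates == 0:
        raise ValueError("empty bootstrap sample")
    taxa = sample.trees[0].taxa
    counts: dict[int, int] = {}
    for tree in sample.trees:
        for mask in tree.split_masks():
            counts[mask] = counts.get(mask, 0) + 1
    return {
        Bipartition.from_mask(m, taxa): c / sample.n_replicates
        for m, c in counts.items()
    }


def mask_support(sample: BootstrapSample, reference_masks) -> dict[int, float]:
    """Support of specific reference split masks (internal fast path)."""
    counts = dict.fromkeys(reference_masks, 0)
    for tree in sample.trees:
        observed = tree.split_masks().keys()
        for mask in counts:
            if mask in observed:
                counts[mask] += 1
    return {m: c / sample.n_replicates for m, c in counts.items()}


def compatible_reference_bipartitions(
    reference: Phylogeny,
    sample: BootstrapSample,
    threshold: float = DEFAULT_RECOVERY_THRESHOLD,
    partition_id: str = "",
    mean_rate: float = np.nan,
) -> pd.DataFrame:
    """Recovery table: one row per reference bipartition with its branch
    length, bootstrap support and recovered flag (support >= threshold)."""
    _check_same_taxa(reference, sample.trees[0])
    taxa = reference.taxa
    ref_masks = reference.split_masks()
    support = mask_support(sample, list(ref_masks))
    rows = [
        {
            "partition": partition_id,
            "mean_rate": mean_rate,
            "bipartition": str(Bipartition.from_mask(m, taxa)),
            "branch_length": ln,
            "support": support[m],
            "recovered": support[m] >= threshold,
        }
        for m, ln in ref_masks.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation helpers
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value: exact permutation below 10
    pairs, large-sample t approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        return np.nan, np.nan
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return np.nan, np.nan
    rx = _stats.rankdata(x)
    ry = _stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n < 10:
        perms = np.array(list(itertools.permutations(ry)))
        cx = rx - rx.mean()
        cp = perms - perms.mean(axis=1, keepdims=True)
        rhos = (cp @ cx) / (
            np.linalg.norm(cp, axis=1) * np.linalg.norm(cx)
        )
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(_stats.spearmanr(x, y).pvalue)
    return rho, p


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def recovery_statistics(table: pd.DataFrame) -> dict:
    """Summary of a recovery table spanning >= 3 partitions.

    Per partition: the median branch length of *recovered* bipartitions,
    the fraction of below-median-branch-length reference bipartitions
    recovered, and the fraction of top-quartile (longest-branch) reference
    bipartitions recovered. Across partitions: Spearman rho between mean
    category rate and the median recovered branch length. The branch-length
    median/quartile cutoffs come from the reference bipartitions, which are
    identical across partitions.
    """
    if table["partition"].nunique() < 3:
        raise ValueError("need at least 3 partitions for recovery statistics")
    ref = table.drop_duplicates("bipartition")
    median_bl = float(ref["branch_length"].median())
    q75_bl = float(ref["branch_length"].quantile(0.75))
    per_partition = []
    for pid, grp in table.groupby("partition", sort=False):
        rec = grp[grp["recovered"]]
        short = grp[grp["branch_length"] < median_bl]
        long_ = grp[grp["branch_length"] >= q75_bl]
        per_partition.append(
            {
                "partition": pid,
                "mean_rate": float(grp["mean_rate"].iloc[0]),
                "n_recovered": int(rec.shape[0]),
                "median_recovered_branch_length": (
                    float(rec["branch_length"].median()) if len(rec) else np.nan
                ),
                "below_median_recovery": (
                    float(short["recovered"].mean()) if len(short) else np.nan
                ),
                "top_quartile_recovery": (
                    float(long_["recovered"].mean()) if len(long_) else np.nan
                ),
            }
        )
    per_partition = pd.DataFrame(per_partition)
    ok = per_partition.dropna(subset=["median_recovered_branch_length"])
    rho, p = spearman(ok["mean_rate"], ok["median_recovered_branch_length"])
    return {
        "per_partition": per_partition,
        "spearman_rho": rho,
        "spearman_p": p,
        "reference_median_branch_length": median_bl,
        "reference_q75_branch_length": q75_bl,
    }


def pooled_rate_branchlength_spearman(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between a partition's mean category rate and the
    branch lengths of its recovered reference bipartitions, pooling the
    (rate, branch length) pairs across partitions."""
    rec = table[table["recovered"]]
    if rec.shape[0] < 3:
        return np.nan, np.nan
    return spearman(rec["mean_rate"], rec["branch_length"])


def rf_slope(sample_distances: dict, rates, category_range=(9, 12)) -> float:
    """OLS slope of mean RF distance on mean category rate over a selected
    range of categories (inclusive, 1-based)."""
    lo, hi = category_range
    cats = [c for c in sorted(sample_distances) if lo <= c <= hi]
    if len(cats) < 2:
        raise ValueError("need at least 2 categories in the selected range")
    x = np.array([rates[c - 1] for c in cats], dtype=float)
    y = np.array([np.mean(sample_distances[c]) for c in cats], dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def mds_embedding(rf_matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres the squared distances, takes the top eigenvectors scaled
    by the square roots of their (non-negative) eigenvalues; axis signs are
    fixed so each axis's largest-magnitude coordinate is positive.
    """
    D = np.asarray(rf_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9) or not np.allclose(np.diag(D), 0, atol=1e-12):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    lam, U = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1][:n_components]
    lam_top = np.clip(lam[order], 0.0, None)
    coords = U[:, order] * np.sqrt(lam_top)[None, :]
    for a in range(coords.shape[1]):  # deterministic sign convention
        col = coords[:, a]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    return coords
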