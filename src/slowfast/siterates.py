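"""Per-site likelihoods under a fixed tree and empirical-Bayes assignment of
sites to discrete-gamma rate categories.

Given a guide tree, site likelihoods are computed by Felsenstein pruning at
each category's rate multiplier; the posterior over the k equiprobable
categories is ``post_c(site) proportional to (1/k) L_site(r_c)`` and each
variable site is hard-binned to its maximum-posterior category (ties go to
the slower category). Invariant columns are flagged first and carry no
category. Gaps and ambiguous residues are fully missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._aa import MISSING, N_AA
from .alignment import Alignment
from .models import (
    GammaRateCategories,
    RateModel,
    discretize_gamma,
    transition_probabilities,
)
from .phylo import Phylogeny


@dataclass
class SiteRateAssignment:
    """Per-site rate-category assignment.

    ``category`` is 1..k for variable sites and 0 for invariant sites;
    ``posterior`` rows of invariant sites are NaN.
    """

    category: np.ndarray
    posterior: np.ndarray
    invariant: np.ndarray
    alpha_used: float
    rates: np.ndarray

    @property
    def n_categories(self) -> int:
        return self.posterior.shape[1]

    def sites_in_category(self, category: int) -> np.ndarray:
        """0-based column indices assigned to one category, ascending."""
        return np.flatnonzero(self.category == category)

    def to_tsv(self, path) -> None:
        """Write a per-site rate table (site, rate, category), mirroring the
        layout of IQTree's .rate files; invariant sites get rate 0."""
        with open(path, "w") as fh:
            fh.write("site\trate\tcategory\n")
            for i, cat in enumerate(self.category, start=1):
                rate = self.rates[cat - 1] if cat > 0 else 0.0
                fh.write(f"{i}\t{rate:.6g}\t{cat}\n")


def _leaf_partials(alignment: Alignment, taxa_needed: list[str]) -> dict[str, np.ndarray]:
    """One-hot leaf partial likelihoods, (n_sites, 20); missing -> all ones."""
    partials = {}
    eye = np.vstack([np.eye(N_AA), np.ones(N_AA)])  # row MISSING = ones
    for taxon in taxa_needed:
        if taxon not in alignment.taxa:
            raise KeyError(f"tree leaf {taxon!r} has no row in the alignment")
        codes = alignment.data[alignment.taxa.index(taxon)]
        partials[taxon] = eye[codes]
    return partials


def _pruning_loglik(
    alignment: Alignment, tree: Phylogeny, model: RateModel, rate: float
) -> np.ndarray:
    """Per-site log-likelihood at one rate multiplier, with per-node
    rescaling to stay in range on large trees."""
    leaves = [n.name for n in tree.leaves()]
    leaf_partials = _leaf_partials(alignment, leaves)
    n_sites = alignment.n_sites
    if tree.root.is_leaf:  # degenerate single-taxon "tree"
        lik = leaf_partials[tree.root.name] @ model.frequencies
        return np.log(lik)
    partial: dict = {}
    logscale = np.zeros(n_sites)
    for node in tree.postorder():
        if node.is_leaf:
            partial[node] = leaf_partials[node.name]
            continue
        acc = np.ones((n_sites, N_AA))
        for child in node.children:
            if child.length is None:
                raise ValueError("tree has a branch without a length")
            P = transition_probabilities(model, child.length, rate)
            acc *= partial.pop(child) @ P.T
        scale = acc.max(axis=1)
        scale[scale == 0.0] = 1.0
        acc /= scale[:, None]
        logscale += np.log(scale)
        partial[node] = acc
    lik = partial[tree.root] @ model.frequencies
    return np.log(lik) + logscale


def site_log_likelihood(
    alignment: Alignment, site: int, tree: Phylogeny, model: RateModel, rate: float = 1.0
) -> float:
    """Log-likelihood of one site pattern under the CTMC at a given rate."""
    return float(_pruning_loglik(alignment.select_sites([site]), tree, model, rate)[0])


def site_category_log_likelihoods(
    alignment: Alignment, tree: Phylogeny, model: RateModel, rates: np.ndarray
) -> np.ndarray:
    """Per-site log-likelihood at every rate multiplier; shape (n_sites, k)."""
    return np.column_stack(
        [_pruning_loglik(alignment, tree, model, r) for r in rates]
    )


def assign_site_categories(
    alignment: Alignment,
    tree: Phylogeny,
    model: RateModel,
    cats: GammaRateCategories,
) -> SiteRateAssignment:
    """Empirical-Bayes hard binning of sites into rate categories."""
    if alignment.n_sites == 0 or alignment.n_taxa == 0:
        raise ValueError("empty alignment")
    invariant = alignment.is_invariant()
    k = cats.n_categories
    n_sites = alignment.n_sites
    posterior = np.full((n_sites, k), np.nan)
    category = np.zeros(n_sites, dtype=int)
    variable = np.flatnonzero(~invariant)
    if variable.size:
        sub = alignment.select_sites(variable)
        ll = site_category_log_likelihoods(sub, tree, model, cats.rates)
        ll -= ll.max(axis=1, keepdims=True)
        w = np.exp(ll)  # equal priors 1/k cancel in the normalisation
        w /= w.sum(axis=1, keepdims=True)
        posterior[variable] = w
        category[variable] = np.argmax(w, axis=1) + 1  # argmax ties -> slower
    return SiteRateAssignment(
        category=category,
        posterior=posterior,
        invariant=invariant,
        alpha_used=cats.alpha,
        rates=np.asarray(cats.rates),
    )


def estimate_alpha(
    alignment: Alignment,
    tree: Phylogeny,
    model: RateModel,
    k: int,
    bounds: tuple[float, float] = (0.05, 20.0),
) -> float:
    """Maximum-likelihood gamma shape under the discrete-gamma mixture,
    holding the tree fixed (bounded 1-D search).

    All sites enter the likelihood: invariant columns carry most of the
    information about the slow tail, and dropping them would bias the
    shape upward.
    """
    invariant = alignment.is_invariant()
    if int((~invariant).sum()) < 2:
        raise ValueError("need at least 2 variable sites to estimate alpha")

    def neg_loglik(alpha: float) -> float:
        rates = discretize_gamma(alpha, k).rates
        ll = site_category_log_likelihoods(alignment, tree, model, rates)
        m = ll.max(axis=1)
        mix = m + np.log(np.exp(ll - m[:, None]).mean(axis=1))
        return -float(mix.sum())

    res = minimize_scalar(
        neg_loglik, bounds=bounds, method="bounded", options={"xatol": 1e-3}
    )
    if not res.success:
        raise RuntimeError(
            f"alpha optimisation failed to converge in {bounds}: {res.message}"
        )
    return float(res.x)
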