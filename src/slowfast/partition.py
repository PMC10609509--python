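"""Substitution-rate-category binning, rate-specific alignment partitions
(RSAPs), trimming schemes, invariant-site removal and gap-context labels.

An RSAP takes every site assigned to one rate category and tandem-replicates
the columns cyclically until a target length is reached, so that partitions
from sparse and dense categories carry the same number of informative sites.
Trimming schemes drop whole category ranges: ``slow_trim`` removes
categories 1-4, ``fast_trim`` removes 10-12, ``both_trim`` removes both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .siterates import SiteRateAssignment


@dataclass(frozen=True)
class RSAP:
    """Rate-specific alignment partition: one category's sites, cyclically
    replicated to a fixed target length."""

    category: int
    source_sites: np.ndarray  # ascending 0-based original column indices
    replicated_alignment: Alignment
    target_length: int


@dataclass(frozen=True)
class TrimScheme:
    """A named set of rate categories to drop before tree inference."""

    name: str
    dropped_categories: frozenset[int]

    SLOW_CATEGORIES = frozenset({1, 2, 3, 4})
    FAST_CATEGORIES = frozenset({10, 11, 12})

    @classmethod
    def named(cls, name: str) -> "TrimScheme":
        table = {
            "none": frozenset(),
            "slow_trim": cls.SLOW_CATEGORIES,
            "fast_trim": cls.FAST_CATEGORIES,
            "both_trim": cls.SLOW_CATEGORIES | cls.FAST_CATEGORIES,
        }
        if name not in table:
            raise ValueError(f"unknown trim scheme {name!r}; choose from {sorted(table)}")
        return cls(name=name, dropped_categories=table[name])


@dataclass(frozen=True)
class GapContext:
    """Thresholds for labelling a column by the gap counts of its flanking
    columns: rich if every flank has >= rich_threshold gaps, poor if every
    flank has <= poor_threshold, else intermediate."""

    rich_threshold: int = 2000
    poor_threshold: int = 500
    window: int = 1

    def __post_init__(self):
        if not self.rich_threshold > self.poor_threshold >= 0:
            raise ValueError("need rich_threshold > poor_threshold >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @classmethod
    def from_fractions(
        cls, n_taxa: int, rich_fraction: float, poor_fraction: float, window: int = 1
    ) -> "GapContext":
        """Scale the absolute gap-count thresholds to an alignment of a
        different depth (the defaults 2000/500 correspond to roughly
        65%/16% of a 3083-taxon alignment)."""
        return cls(
            rich_threshold=int(round(rich_fraction * n_taxa)),
            poor_threshold=int(round(poor_fraction * n_taxa)),
            window=window,
        )


def remove_invariant_sites(alignment: Alignment) -> tuple[Alignment, np.ndarray]:
    """Drop columns with at most one distinct non-gap residue.

    Returns the variable-site alignment and the 0-based indices of the
    removed columns (ascending).
    """
    invariant = alignment.is_invariant()
    keep = np.flatnonzero(~invariant)
    return alignment.select_sites(keep), np.flatnonzero(invariant)


def bin_sites(assignment: SiteRateAssignment) -> list[np.ndarray]:
    """Per-category lists of 0-based column indices (ascending), one per
    rate category; empty bins are allowed."""
    return [assignment.sites_in_category(c) for c in range(1, assignment.n_categories + 1)]


def build_rsap(
    alignment: Alignment, sites, target_length: int, category: int = 0
) -> RSAP:
    """Tandem-replicate a category's sites cyclically to the target length."""
    sites = np.asarray(sites, dtype=int)
    if sites.size == 0:
        raise ValueError(f"category {category} has no sites; cannot build an RSAP")
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    sites = np.sort(sites)
    columns = sites[np.arange(target_length) % sites.size]
    return RSAP(
        category=category,
        source_sites=sites,
        replicated_alignment=alignment.select_sites(columns),
        target_length=int(target_length),
    )


def apply_trim(
    alignment: Alignment, assignment: SiteRateAssignment, scheme: TrimScheme
) -> tuple[Alignment, dict]:
    """Remove all columns whose category falls in the scheme; order is
    preserved. Returns the trimmed alignment and a site-count report."""
    dropped_mask = np.isin(assignment.category, list(scheme.dropped_categories))
    keep = np.flatnonzero(~dropped_mask)
    report = {
        "scheme": scheme.name,
        "n_input_sites": alignment.n_sites,
        "n_removed": int(dropped_mask.sum()),
        "n_kept": int(keep.size),
        "kept_fraction": float(keep.size / alignment.n_sites) if alignment.n_sites else 0.0,
    }
    return alignment.select_sites(keep), report


def classify_gap_context(alignment: Alignment, context: GapContext | None = None) -> np.ndarray:
    """Label every column rich / poor / intermediate by the gap counts of
    its flanking columns (window columns on each side; terminal columns use
    only the existing side)."""
    context = context or GapContext()
    gaps = alignment.gap_counts()
    n = alignment.n_sites
    labels = np.empty(n, dtype=object)
    for j in range(n):
        flanks = np.concatenate(
            [gaps[max(0, j - context.window) : j], gaps[j + 1 : j + 1 + context.window]]
        )
        if flanks.size == 0:  # single-column alignment: no flanks to judge
            labels[j] = "intermediate"
        elif np.all(flanks >= context.rich_threshold):
            labels[j] = "rich"
        elif np.all(flanks <= context.poor_threshold):
            labels[j] = "poor"
        else:
            labels[j] = "intermediate"
    return labels


def subsample_sites(sites, n: int, seed) -> np.ndarray:
    """Seeded random subsample of a site list without replacement,
    returned ascending (used to match partition sizes across conditions)."""
    sites = np.asarray(sites, dtype=int)
    if n > sites.size:
        raise ValueError(f"cannot subsample {n} of {sites.size} sites")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(sites, size=n, replace=False))
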