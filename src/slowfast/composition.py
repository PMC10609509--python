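"""Amino-acid composition per alignment partition and the compositional-bias
sum-of-squared-errors statistic (per-residue frequency deviation of a
partition from the whole alignment)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._aa import AA_ORDER, MISSING, N_AA
from .alignment import Alignment


@dataclass(frozen=True)
class CompositionProfile:
    """Residue frequencies of one partition (gaps excluded)."""

    frequencies: np.ndarray
    n_residues: int
    partition: str = ""


def aa_frequencies(alignment: Alignment, partition: str = "") -> CompositionProfile:
    """Residue counts over all non-gap cells, normalised to frequencies."""
    counts = np.bincount(alignment.data[alignment.data != MISSING], minlength=N_AA)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("alignment contains no residues (all gaps)")
    return CompositionProfile(
        frequencies=counts / total, n_residues=total, partition=partition
    )


def composition_sse(partition: CompositionProfile, whole: CompositionProfile) -> float:
    """Sum over the 20 residues of the squared frequency deviation."""
    d = partition.frequencies - whole.frequencies
    return float(np.dot(d, d))


def composition_table(
    profiles: list[CompositionProfile], whole: CompositionProfile
) -> pd.DataFrame:
    """One row per partition: 20 residue frequencies, residue count, SSE."""
    rows = []
    for prof in profiles:
        row = {"partition": prof.partition, "n_residues": prof.n_residues}
        row.update({aa: f for aa, f in zip(AA_ORDER, prof.frequencies)})
        row["sse"] = composition_sse(prof, whole)
        rows.append(row)
    return pd.DataFrame(rows)
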