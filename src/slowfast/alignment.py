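"""Amino-acid alignment container with gap handling and FASTA I/O."""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._aa import MISSING, decode, encode


class Alignment:
    """A taxa x sites amino-acid matrix.

    Residues are uint8 codes 0..19 (PAML order); 20 marks a gap or an
    ambiguous residue (B/Z/X etc.), both treated as missing data.
    """

    def __init__(self, taxa: list[str], data: np.ndarray):
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2 or data.shape[0] != len(taxa):
            raise ValueError(
                f"data must be (n_taxa, n_sites); got {data.shape} for {len(taxa)} taxa"
            )
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in alignment")
        self.taxa = list(taxa)
        self.data = data

    # -- basic properties ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.n_sites

    def sequence(self, taxon: str) -> str:
        return decode(self.data[self.taxa.index(taxon)])

    def column(self, site: int) -> np.ndarray:
        """Residue codes of one 0-based column."""
        return self.data[:, site]

    # -- derived matrices ---------------------------------------------------
    def gap_counts(self) -> np.ndarray:
        """Per-column count of missing cells."""
        return (self.data == MISSING).sum(axis=0)

    def is_invariant(self) -> np.ndarray:
        """Per-column flag: at most one distinct non-gap residue (gaps
        ignored, so an all-gap column is also invariant)."""
        flags = np.empty(self.n_sites, dtype=bool)
        for j in range(self.n_sites):
            col = self.data[:, j]
            residues = np.unique(col[col != MISSING])
            flags[j] = residues.size <= 1
        return flags

    # -- subsetting ---------------------------------------------------------
    def select_sites(self, sites) -> "Alignment":
        sites = np.asarray(sites, dtype=int)
        return Alignment(self.taxa, self.data[:, sites])

    def select_taxa(self, taxa: list[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.data[idx])

    # -- IO -----------------------------------------------------------------
    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "Alignment":
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        data = np.stack([encode(sequences[t]) for t in taxa])
        return cls(taxa, data)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_sequences({r.id: str(r.seq) for r in records})

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(decode(row)), id=taxon, description="")
            for taxon, row in zip(self.taxa, self.data)
        ]
        SeqIO.write(records, str(path), "fasta")
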