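"""Amino-acid alphabet and encoding shared across the package.

Residues are stored as uint8 codes 0..19 in the PAML/WAG ordering
(A R N D C Q E G H I L K M F P S T W Y V); code 20 marks a gap or any
ambiguous residue (B, Z, X, '-', '.', '?', '*'), all treated as fully
missing data.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
N_AA = 20
MISSING = 20  # gap / ambiguous code

_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _a in enumerate(AA_ORDER):
    _CODE[ord(_a)] = _i
    _CODE[ord(_a.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string to uint8 codes (unknowns -> MISSING)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to a string; MISSING becomes '-'."""
    lut = np.frombuffer((AA_ORDER + "-").encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")
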