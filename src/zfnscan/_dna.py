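"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_acgt(seq: str) -> bool:
    return not (set(seq) - ACGT)


# Byte lookup table: A,C,G,T -> 0..3, everything else (incl. N) -> 4.
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_strict(seq: str) -> np.ndarray:
    codes = encode(seq)
    if (codes >= 4).any():
        bad = sorted(set(seq) - ACGT)
        raise ValueError(f"non-ACGT character(s) {bad} in sequence")
    return codes
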