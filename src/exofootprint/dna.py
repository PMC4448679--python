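"""Shared DNA alphabet utilities."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

#: IUPAC degeneracy codes mapped to the set of plain bases they admit.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes 0..3 for A,C,G,T; anything else is 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes) -> str:
    """Inverse of :func:`encode` for codes in 0..3."""
    return _DEC[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC degeneracy codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]
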