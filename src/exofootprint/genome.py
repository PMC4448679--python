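"""Uniform access to reference sequence from dicts or indexed FASTA."""

from __future__ import annotations

from pathlib import Path

import pyfaidx


class Genome:
    """Thin adapter over a ``{chrom: sequence}`` dict or a pyfaidx Fasta."""

    def __init__(self, source):
        self._src = source
        self._is_dict = isinstance(source, dict)

    @classmethod
    def of(cls, obj) -> "Genome":
        if isinstance(obj, Genome):
            return obj
        if isinstance(obj, (str, Path)):
            return cls(pyfaidx.Fasta(str(obj), sequence_always_upper=True))
        return cls(obj)

    def __contains__(self, chrom: str) -> bool:
        if self._is_dict:
            return chrom in self._src
        try:
            self._src[chrom]
            return True
        except KeyError:
            return False

    def keys(self):
        return list(self._src.keys())

    def length(self, chrom: str) -> int:
        return len(self._src[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), uppercase; clipped at chromosome ends."""
        start = max(0, start)
        seq = self._src[chrom][start:end]
        return str(seq).upper()


def load_genome(path) -> Genome:
    """Open an (indexed) FASTA file; the .fai index is created if absent."""
    return Genome.of(path)
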