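"""Genomic intervals and simple read records.

Coordinates are 0-based half-open throughout, as in BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class SimRead(NamedTuple):
    """A mapped single-end read: half-open interval plus strand."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    name: str = ""


def site_anchor(start: int, end: int, strand: str) -> int:
    """Genomic bp of the motif-oriented center of a site.

    The anchor is the floor-center measured along the motif's own 5'->3'
    axis: ``start + L//2`` on "+", ``end - 1 - L//2`` on "-". For odd
    motif lengths the two coincide; defining the center motif-side keeps
    profile extraction exactly mirror-symmetric for even lengths too.
    """
    half = (end - start) // 2
    return end - 1 - half if strand == "-" else start + half


def mirror_interval(iv: GenomicInterval, chrom_length: int) -> GenomicInterval:
    """Interval coordinates after reverse-complementing the chromosome."""
    flip = {"+": "-", "-": "+", ".": "."}
    return GenomicInterval(
        iv.chrom, chrom_length - iv.end, chrom_length - iv.start, flip[iv.strand]
    )


def mirror_read(read: SimRead, chrom_length: int) -> SimRead:
    """Read coordinates after reverse-complementing the chromosome."""
    flip = {"+": "-", "-": "+"}
    return SimRead(
        read.chrom,
        chrom_length - read.end,
        chrom_length - read.start,
        flip[read.strand],
        read.mapq,
        read.name,
    )
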