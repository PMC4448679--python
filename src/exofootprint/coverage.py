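"""Strand-specific 5'-end read coverage and motif-anchored profiles.

ChIP-exo resolution comes from the lambda exonuclease stopping a few bp
upstream of the protein:DNA cross-link, so only the most 5' base of each
read is informative: a plus-strand read contributes at its start, a
minus-strand read at ``end - 1``. Profiles are extracted in motif
orientation: for a site matched on the minus strand the window is
position-reversed and strand-swapped, so "forward" always means the
strand carrying the motif as matched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import SimRead
from .scan import MotifHit

logger = logging.getLogger(__name__)

_STRANDS = ("+", "-")


class FivePrimeIndex:
    """Per-chromosome, per-strand counts of read 5' ends."""

    def __init__(self):
        self._counts: dict[tuple[str, str], dict[int, int]] = {}
        self.n_reads: int = 0

    def add_five_prime(self, chrom: str, strand: str, pos: int, k: int = 1) -> None:
        if strand not in _STRANDS:
            raise ValueError(f"unknown strand symbol {strand!r}")
        bucket = self._counts.setdefault((chrom, strand), {})
        bucket[pos] = bucket.get(pos, 0) + k
        self.n_reads += k

    def add_read(self, chrom: str, start: int, end: int, strand: str) -> None:
        """Count a read at its 5' base: start on '+', end-1 on '-'."""
        if strand == "+":
            self.add_five_prime(chrom, "+", start)
        elif strand == "-":
            self.add_five_prime(chrom, "-", end - 1)
        else:
            raise ValueError(f"unknown strand symbol {strand!r}")

    def count(self, chrom: str, strand: str, pos: int) -> int:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Counts for positions [start, end); off-chromosome bp are zero."""
        bucket = self._counts.get((chrom, strand))
        out = np.zeros(end - start, dtype=float)
        if bucket:
            get = bucket.get
            for i, pos in enumerate(range(start, end)):
                v = get(pos)
                if v:
                    out[i] = v
        return out

    def total(self) -> int:
        return sum(sum(b.values()) for b in self._counts.values())

    def positions(self, chrom: str, strand: str) -> dict[int, int]:
        return dict(self._counts.get((chrom, strand), {}))

    def scaled(self, factor: float) -> "FivePrimeIndex":
        """A copy with every count multiplied by ``factor`` (for invariance checks)."""
        out = FivePrimeIndex()
        for (chrom, strand), bucket in self._counts.items():
            for pos, v in bucket.items():
                out.add_five_prime(chrom, strand, pos, k=v * factor)
        return out


def _iter_alignment_file(path, min_mapq):
    import pysam

    paired_warned = False
    with pysam.AlignmentFile(str(path)) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if (aln.mapping_quality or 0) < min_mapq:
                continue
            if aln.is_paired and not paired_warned:
                warnings.warn(
                    "paired-end reads found; mates are counted as independent "
                    "single-end reads",
                    stacklevel=3,
                )
                paired_warned = True
            yield (
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
                aln.mapping_quality,
            )


def _iter_bed_reads(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 read record needs 6 columns")
            score = fields[4]
            mapq = int(float(score)) if score not in (".", "") else 60
            yield fields[0], int(fields[1]), int(fields[2]), fields[5], mapq


def build_five_prime_index(
    reads,
    min_mapq: int = 1,
    dedup: bool = False,
) -> FivePrimeIndex:
    """Index read 5' ends from a BAM/SAM path, BED6 path, or iterable.

    Reads below ``min_mapq`` and unmapped/secondary/supplementary
    alignments are skipped. With ``dedup``, identical
    (chrom, strand, 5' bp, 3' bp) tuples are counted once; the default
    keeps duplicates because exonuclease stops legitimately stack at
    identical positions.
    """
    if isinstance(reads, (str, Path)):
        suffix = Path(reads).suffix.lower()
        if suffix in (".bam", ".sam", ".cram"):
            source = _iter_alignment_file(reads, min_mapq)
        elif suffix in (".bed", ".bed6"):
            source = (
                r for r in _iter_bed_reads(reads) if r[4] >= min_mapq
            )
        else:
            raise ValueError(f"cannot infer read format from suffix {suffix!r}")
    else:
        def _gen():
            for r in reads:
                if isinstance(r, SimRead):
                    tup = (r.chrom, r.start, r.end, r.strand, r.mapq)
                elif isinstance(r, (tuple, list)):
                    tup = (r[0], r[1], r[2], r[3], r[4] if len(r) > 4 else 60)
                else:
                    tup = (r.chrom, r.start, r.end, r.strand, getattr(r, "mapq", 60))
                if tup[4] >= min_mapq:
                    yield tup

        source = _gen()

    index = FivePrimeIndex()
    seen: set[tuple] = set()
    for chrom, start, end, strand, _mapq in source:
        if dedup:
            key = (chrom, strand, start, end)
            if key in seen:
                continue
            seen.add(key)
        index.add_read(chrom, start, end, strand)
    return index


@dataclass
class ProfileMatrix:
    """Per-site, per-relative-position, per-oriented-strand 5' counts.

    ``values`` has shape (n_sites, L + 2F, 2); the last axis is
    (forward, reverse) in motif orientation. ``positions`` is the
    relative bp axis, from ``-F - L//2`` to ``F + ceil(L/2) - 1``.
    """

    sites: list[MotifHit]
    flank: int
    motif_length: int
    positions: np.ndarray
    values: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def site_totals(self) -> np.ndarray:
        return self.values.sum(axis=(1, 2))

    def subset(self, indices) -> "ProfileMatrix":
        idx = np.asarray(indices)
        return ProfileMatrix(
            sites=[self.sites[i] for i in idx],
            flank=self.flank,
            motif_length=self.motif_length,
            positions=self.positions.copy(),
            values=self.values[idx].copy(),
        )

    @classmethod
    def concat(cls, matrices: Sequence["ProfileMatrix"]) -> "ProfileMatrix":
        first = matrices[0]
        for m in matrices[1:]:
            if not np.array_equal(m.positions, first.positions):
                raise ValueError("position axes differ; cannot concatenate")
        return cls(
            sites=[s for m in matrices for s in m.sites],
            flank=first.flank,
            motif_length=first.motif_length,
            positions=first.positions.copy(),
            values=np.concatenate([m.values for m in matrices], axis=0),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per site with per-position counts per strand."""
        rows = {
            "chrom": [h.site.chrom for h in self.sites],
            "start": [h.site.start for h in self.sites],
            "end": [h.site.end for h in self.sites],
            "strand": [h.site.strand for h in self.sites],
            "motif_id": [h.motif_id for h in self.sites],
        }
        fwd = pd.DataFrame(
            self.values[:, :, 0], columns=[f"fwd_{r}" for r in self.positions]
        )
        rev = pd.DataFrame(
            self.values[:, :, 1], columns=[f"rev_{r}" for r in self.positions]
        )
        return pd.concat([pd.DataFrame(rows), fwd, rev], axis=1)


@dataclass
class FootprintProfile:
    """Per-position summed 5' coverage for each oriented strand."""

    positions: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray
    n_sites: int

    def total(self) -> float:
        return float(self.forward.sum() + self.reverse.sum())

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean coverage per site (zero arrays when no sites matched)."""
        if self.n_sites == 0:
            return np.zeros_like(self.forward), np.zeros_like(self.reverse)
        return self.forward / self.n_sites, self.reverse / self.n_sites

    def normalized_total(self) -> float:
        return self.total() / self.n_sites if self.n_sites else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "forward": self.forward, "reverse": self.reverse}
        )


def profile_positions(motif_length: int, flank: int) -> np.ndarray:
    """Relative coordinate axis for a motif of length L with flank F."""
    L = motif_length
    return np.arange(-(flank + L // 2), flank + (L - L // 2))


def site_coverage_matrix(
    index: FivePrimeIndex,
    hits: Sequence[MotifHit],
    flank: int = 30,
) -> ProfileMatrix:
    """Extract orientation-normalized 5' count windows around each hit.

    For a + site, value(r, s) is the index count at (anchor + r, s); for
    a - site the window is position-reversed and strand-swapped:
    value(r, forward) is the count at (anchor - r) on the genomic
    reverse strand. Off-chromosome positions contribute zeros.
    """
    if not hits:
        raise ValueError("hits must be non-empty")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    L = hits[0].length
    if any(h.length != L for h in hits):
        raise ValueError("all hits must share one motif length")
    positions = profile_positions(L, flank)
    r0, r1 = int(positions[0]), int(positions[-1])
    values = np.zeros((len(hits), positions.size, 2))
    for i, h in enumerate(hits):
        a = h.anchor
        chrom = h.site.chrom
        if h.site.strand == "-":
            values[i, :, 0] = index.window(chrom, "-", a - r1, a - r0 + 1)[::-1]
            values[i, :, 1] = index.window(chrom, "+", a - r1, a - r0 + 1)[::-1]
        else:
            values[i, :, 0] = index.window(chrom, "+", a + r0, a + r1 + 1)
            values[i, :, 1] = index.window(chrom, "-", a + r0, a + r1 + 1)
    return ProfileMatrix(
        sites=list(hits),
        flank=flank,
        motif_length=L,
        positions=positions,
        values=values,
    )


def aggregate_footprint(matrix: ProfileMatrix) -> FootprintProfile:
    """Sum the per-site windows into a footprint profile."""
    if matrix.n_sites == 0:
        raise ValueError("cannot aggregate an empty profile matrix")
    return FootprintProfile(
        positions=matrix.positions.copy(),
        forward=matrix.values[:, :, 0].sum(axis=0),
        reverse=matrix.values[:, :, 1].sum(axis=0),
        n_sites=matrix.n_sites,
    )
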