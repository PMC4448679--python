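"""Scan bound regions for motif matches and classify regions by content.

Both strands of every region are scored; reverse-strand matches are
reported with the matched sequence on the motif strand. Scores are
compared on the same discretization lattice the exact p-value dynamic
programme uses, so a hit is reported iff its discretized score reaches
the discretized threshold.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .dna import revcomp
from .genome import Genome
from .intervals import GenomicInterval, site_anchor
from .motifs import SCORE_GRID, ConsensusPattern, PositionWeightMatrix


@dataclass(frozen=True)
class MotifHit:
    """A located, stranded motif match inside a bound region."""

    region: GenomicInterval
    site: GenomicInterval
    motif_id: str
    matched_seq: str
    score: float | None = None

    def __post_init__(self):
        if not self.region.contains(self.site):
            raise ValueError(f"site {self.site} not inside region {self.region}")
        if len(self.matched_seq) != self.site.length:
            raise ValueError("matched_seq length differs from site width")

    @property
    def length(self) -> int:
        return self.site.length

    @property
    def anchor(self) -> int:
        """Genomic bp of the motif-oriented site center."""
        return site_anchor(self.site.start, self.site.end, self.site.strand)


def _window_scores(codes: np.ndarray, lattice: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lattice scores of every window on both strands.

    Returns (scores, valid) where scores has shape (2, n_windows) with
    row 0 = forward, row 1 = reverse (score of the reverse-complemented
    window), and valid flags windows free of non-ACGT symbols.
    """
    L = lattice.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty((2, 0), dtype=np.int64), np.empty(0, dtype=bool)
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[L:] - cum[:-L]) == 0
    safe = np.where(codes < 4, codes, 0)
    # score of the reverse complement, accumulated on forward coordinates
    lat_rc = lattice[::-1, ::-1]
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(L):
        col = safe[j : j + n]
        fwd += lattice[j][col]
        rev += lat_rc[j][col]
    return np.stack([fwd, rev]), valid


def _resolve_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Greedy same-motif overlap resolution.

    Higher score wins; on ties the + strand wins, then the leftmost
    site. Palindromic double-hits (same coordinates, both strands,
    equal score) therefore keep the + strand.
    """
    by_group: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        by_group.setdefault((h.motif_id, h.site.chrom), []).append(h)
    kept: list[MotifHit] = []
    for group in by_group.values():
        group.sort(
            key=lambda h: (
                -(h.score if h.score is not None else 0.0),
                0 if h.site.strand == "+" else 1,
                h.site.start,
            )
        )
        starts: list[int] = []
        ends: list[int] = []
        for h in group:
            i = bisect.bisect_right(starts, h.site.start)
            if i > 0 and ends[i - 1] > h.site.start:
                continue
            if i < len(starts) and starts[i] < h.site.end:
                continue
            starts.insert(i, h.site.start)
            ends.insert(i, h.site.end)
            kept.append(h)
    return kept


def _sorted_hits(hits: list[MotifHit]) -> list[MotifHit]:
    return sorted(hits, key=lambda h: (h.site.chrom, h.site.start, h.site.strand))


def scan_regions(
    genome,
    regions: Iterable[GenomicInterval],
    pwm: PositionWeightMatrix,
    p: float,
    resolve_overlaps: bool = True,
) -> list[MotifHit]:
    """All motif matches at match p-value <= ``p`` inside ``regions``.

    Windows containing non-ACGT symbols are skipped. Overlapping
    same-motif hits are greedily resolved (highest score wins) unless
    ``resolve_overlaps`` is False. Hits are sorted by (chrom, start).
    """
    g = Genome.of(genome)
    t_lat = pwm.threshold_lattice(p)
    lattice = pwm.lattice
    L = pwm.length
    hits: list[MotifHit] = []
    for region in regions:
        if region.chrom not in g:
            raise KeyError(
                f"region {region.chrom}:{region.start}-{region.end}: "
                f"chromosome {region.chrom!r} not in genome"
            )
        seq = g.fetch(region.chrom, region.start, region.end)
        from .dna import encode  # local import keeps module init cheap

        scores, valid = _window_scores(encode(seq), lattice)
        for srow, strand in ((0, "+"), (1, "-")):
            for i in np.nonzero((scores[srow] >= t_lat) & valid)[0]:
                start = region.start + int(i)
                window = seq[int(i) : int(i) + L]
                hits.append(
                    MotifHit(
                        region=region,
                        site=GenomicInterval(region.chrom, start, start + L, strand),
                        motif_id=pwm.motif_id,
                        matched_seq=window if strand == "+" else revcomp(window),
                        score=float(scores[srow, i]) * SCORE_GRID,
                    )
                )
    if resolve_overlaps:
        hits = _resolve_overlaps(hits)
    return _sorted_hits(hits)


def scan_regions_consensus(
    genome,
    regions: Iterable[GenomicInterval],
    pattern: ConsensusPattern,
) -> list[MotifHit]:
    """All windows satisfying the constrained/anti consensus match.

    Both strands are tested (the reverse strand via the reverse
    complement of the window). No overlap resolution is applied, so a
    sequence that satisfies the pattern in both orientations yields two
    hits at the same coordinates.
    """
    g = Genome.of(genome)
    L = pattern.length
    hits: list[MotifHit] = []
    for region in regions:
        if region.chrom not in g:
            raise KeyError(
                f"region {region.chrom}:{region.start}-{region.end}: "
                f"chromosome {region.chrom!r} not in genome"
            )
        seq = g.fetch(region.chrom, region.start, region.end)
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if any(ch not in "ACGT" for ch in window):
                continue
            start = region.start + i
            if pattern.matches(window):
                hits.append(
                    MotifHit(
                        region=region,
                        site=GenomicInterval(region.chrom, start, start + L, "+"),
                        motif_id=pattern.pattern,
                        matched_seq=window,
                    )
                )
            rc = revcomp(window)
            if pattern.matches(rc):
                hits.append(
                    MotifHit(
                        region=region,
                        site=GenomicInterval(region.chrom, start, start + L, "-"),
                        motif_id=pattern.pattern,
                        matched_seq=rc,
                    )
                )
    return _sorted_hits(hits)


def classify_regions_by_motifs(
    regions: list[GenomicInterval],
    hits_a: Iterable[MotifHit],
    hits_b: Iterable[MotifHit],
) -> dict[str, int]:
    """Partition regions by motif content: A_only / B_only / both / neither."""
    known = set(regions)
    has_a: set[GenomicInterval] = set()
    has_b: set[GenomicInterval] = set()
    for hits, bag in ((hits_a, has_a), (hits_b, has_b)):
        for h in hits:
            if h.region not in known:
                raise ValueError(f"hit references unknown region {h.region}")
            bag.add(h.region)
    counts = {"A_only": 0, "B_only": 0, "both": 0, "neither": 0}
    for r in regions:
        a, b = r in has_a, r in has_b
        key = "both" if a and b else "A_only" if a else "B_only" if b else "neither"
        counts[key] += 1
    return counts
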