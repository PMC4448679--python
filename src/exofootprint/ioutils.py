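"""Readers and writers for BED, FASTA, read files, and hit tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, SimRead
from .scan import MotifHit


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (half-open, 0-based)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs at least 3 columns")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads_bed(reads: Iterable[SimRead], path) -> None:
    """Reads as BED6; the score column carries the mapping quality."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{r.mapq}\t{r.strand}\n")


def read_reads_bed(path) -> list[SimRead]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 read record needs 6 columns")
            out.append(
                SimRead(f[0], int(f[1]), int(f[2]), f[5], int(float(f[4])), f[3])
            )
    return out


def write_reads_bam(reads: Sequence[SimRead], chrom_lengths: dict[str, int], path) -> None:
    """Coordinate-sorted, indexed BAM of simulated reads."""
    import pysam

    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    order = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i, r in enumerate(sorted(reads, key=lambda x: (order[x.chrom], x.start))):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name or f"read{i}"
            a.reference_id = order[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = f"{r.end - r.start}M"
            a.query_sequence = "N" * (r.end - r.start)
            a.flag = 16 if r.strand == "-" else 0
            out.write(a)
    pysam.index(str(path))


def hits_to_bed(hits: Sequence[MotifHit], path) -> None:
    """Hits as BED6 (name = motif id, score = 10x log-odds clipped to [0, 1000])."""
    with open(path, "w") as fh:
        for h in hits:
            score = 0 if h.score is None else int(np.clip(round(h.score * 10), 0, 1000))
            fh.write(
                f"{h.site.chrom}\t{h.site.start}\t{h.site.end}\t"
                f"{h.motif_id}\t{score}\t{h.site.strand}\n"
            )
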