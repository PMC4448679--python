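"""Synthetic ChIP-exo data with known cross-link geometry.

The generator emulates what the analysis consumes: a random genome with
one motif instance planted at the center of each non-overlapping "peak"
region, and single-end reads whose 5' ends mark exonuclease stops. Each
signal read picks a cross-link scenario (an offset from the site anchor
and the strand it protects, mirroring the one-or-both-monomers
cross-linking picture), then places its 5' end a sampled stop distance
*upstream of the cross-link on the protected strand's own 5'->3' axis* —
5-6 bp by default, the spacing reported for lambda exonuclease stops.
Upstream means a smaller coordinate on the forward strand and a larger
one on the reverse strand; this single convention fixes all sign
handling. Background reads are uniform in position and strand.

Every emitted read is recorded in a truth table, so each pipeline stage
can be checked against the generating plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dna import BASES, IUPAC, decode, encode, revcomp
from .intervals import GenomicInterval, SimRead, site_anchor
from .motifs import ConsensusPattern, PositionWeightMatrix, pwm_from_consensus

#: The glucocorticoid-receptor binding sequence: an inverted repeat of
#: hexamer half-sites around a 3-bp spacer, 8 informative positions.
GBS_CONSENSUS = "NGNACANNNTGTNCN"

#: Default cross-link scenario mixture for a GBS-like dimer. The two
#: "outer" components are the main cross-link of each monomer protecting
#: the strand approached from outside the site; the lighter "inner"
#: components are the same cross-link points protecting the opposite
#: strand when only one monomer is cross-linked.
GBS_CROSSLINK_MIX = (
    (-8, "+", 0.35),
    (8, "-", 0.35),
    (8, "+", 0.15),
    (-8, "-", 0.15),
)


def gbs_pwm(strength: float = 0.85, motif_id: str = "GBS") -> PositionWeightMatrix:
    """Soft PWM over the GBS consensus; spacer columns are uniform."""
    return pwm_from_consensus(GBS_CONSENSUS, strength=strength, motif_id=motif_id)


def gbs_pattern(
    constrained: Sequence[int] | None = None,
    anti_positions: Sequence[int] = (),
) -> ConsensusPattern:
    """GBS consensus pattern; all 8 non-N positions constrained by default."""
    pat = ConsensusPattern(GBS_CONSENSUS)
    if constrained is None:
        constrained = sorted(pat.non_n_positions() - frozenset(anti_positions))
    return ConsensusPattern(GBS_CONSENSUS, frozenset(constrained), frozenset(anti_positions))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``crosslink_offsets`` is a mixture of (offset bp from the anchor in
    motif orientation, protected strand in motif orientation, weight)
    tuples; weights must sum to 1. ``stop_offset`` is the exonuclease
    stop distance upstream of the cross-link, either a fixed int or an
    inclusive (lo, hi) range sampled uniformly.
    """

    genome_length: int = 120_000
    n_peaks: int = 200
    peak_width: int = 400
    motif: PositionWeightMatrix | ConsensusPattern = field(default_factory=gbs_pwm)
    site_strand_prob: float = 0.5
    crosslink_offsets: tuple = GBS_CROSSLINK_MIX
    stop_offset: int | tuple[int, int] = (5, 6)
    reads_per_site: float = 20.0
    background_rate: float = 0.001
    read_length: int = 36
    seed: int = 0
    chrom: str = "sim1"
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    plant_mode: str = "consensus"  # or "sample" (PWM only)
    plant_sites: bool = True
    planted_sequences: Sequence[str] | None = None
    second_motif: PositionWeightMatrix | ConsensusPattern | None = None
    class_probs: tuple = (0.25, 0.25, 0.25, 0.25)  # A_only, B_only, both, neither

    def __post_init__(self):
        w = sum(c[2] for c in self.crosslink_offsets)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"crosslink weights must sum to 1, got {w}")
        if any(c[2] < 0 for c in self.crosslink_offsets):
            raise ValueError("crosslink weights must be non-negative")
        lo, hi = self.stop_range
        if lo < 0 or hi < lo:
            raise ValueError("stop_offset must be >= 0 (and lo <= hi for a range)")
        if self.background_rate < 0 or self.reads_per_site < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.site_strand_prob <= 1:
            raise ValueError("site_strand_prob must be a probability")

    @property
    def stop_range(self) -> tuple[int, int]:
        if isinstance(self.stop_offset, tuple):
            return self.stop_offset
        return (self.stop_offset, self.stop_offset)

    def motif_length(self) -> int:
        return self.motif.length


@dataclass
class SyntheticTruth:
    """Generating plan: per-site and per-read records."""

    sites: pd.DataFrame
    reads: pd.DataFrame | None = None
    region_classes: pd.DataFrame | None = None


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    peaks: list[GenomicInterval]
    truth: SyntheticTruth
    reads: list[SimRead] | None = None


def _motif_len(motif) -> int:
    return motif.length


def _planted_sequence(motif, mode: str, rng: np.random.Generator) -> str:
    if isinstance(motif, PositionWeightMatrix):
        if mode == "sample":
            return decode([rng.choice(4, p=motif.probs[i]) for i in range(motif.length)])
        return motif.consensus
    # consensus pattern: satisfy every constrained and anti position
    out = []
    for i, code in enumerate(motif.pattern):
        pos = i + 1
        allowed = sorted(IUPAC[code])
        if pos in motif.constrained:
            out.append(allowed[0])
        elif pos in motif.anti_positions:
            out.append(sorted(set(BASES) - IUPAC[code])[0])
        else:
            out.append(BASES[rng.integers(4)])
    return "".join(out)


def simulate_genome_with_sites(cfg: SimConfig) -> SimData:
    """Random genome + non-overlapping peaks with centered planted sites.

    Peaks are laid out one per equal-width slot at a random in-slot
    offset, so they can never overlap; an error is raised if a slot is
    narrower than the peak. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    L = cfg.motif_length()
    max_off = max(abs(c[0]) for c in cfg.crosslink_offsets)
    margin = L + 2 * (max_off + cfg.stop_range[1])
    if cfg.plant_sites and cfg.peak_width < margin:
        raise ValueError(
            f"peak_width {cfg.peak_width} < motif length + 2*(max offset + max stop) = {margin}"
        )
    slot = cfg.genome_length // cfg.n_peaks
    if slot < cfg.peak_width:
        raise ValueError(
            f"cannot place {cfg.n_peaks} non-overlapping peaks of width "
            f"{cfg.peak_width} in {cfg.genome_length} bp"
        )
    codes = rng.choice(4, size=cfg.genome_length, p=np.asarray(cfg.background, float))
    peaks: list[GenomicInterval] = []
    site_rows: list[dict] = []
    class_rows: list[dict] = []
    class_names = ("A_only", "B_only", "both", "neither")
    for i in range(cfg.n_peaks):
        off = int(rng.integers(0, slot - cfg.peak_width + 1))
        start = i * slot + off
        peak = GenomicInterval(cfg.chrom, start, start + cfg.peak_width)
        peaks.append(peak)
        if not cfg.plant_sites:
            continue
        if cfg.second_motif is None:
            plan = [(cfg.motif, start + (cfg.peak_width - L) // 2, "A")]
            label = "A_only"
        else:
            cls = class_names[int(rng.choice(4, p=np.asarray(cfg.class_probs, float)))]
            label = cls
            plan = []
            la, lb = cfg.motif_length(), cfg.second_motif.length
            if cls in ("A_only", "both"):
                plan.append((cfg.motif, start + cfg.peak_width // 4 - la // 2, "A"))
            if cls in ("B_only", "both"):
                plan.append((cfg.second_motif, start + 3 * cfg.peak_width // 4 - lb // 2, "B"))
            class_rows.append(
                {"chrom": peak.chrom, "start": peak.start, "end": peak.end, "class": cls}
            )
        for motif, s0, which in plan:
            ml = motif.length
            strand = "-" if rng.random() < cfg.site_strand_prob else "+"
            if cfg.planted_sequences is not None and which == "A":
                seq = cfg.planted_sequences[i % len(cfg.planted_sequences)].upper()
                if len(seq) != ml:
                    raise ValueError("planted sequence length differs from motif length")
            else:
                seq = _planted_sequence(motif, cfg.plant_mode, rng)
            genomic = revcomp(seq) if strand == "-" else seq
            codes[s0 : s0 + ml] = encode(genomic)
            site_rows.append(
                {
                    "site_id": len(site_rows),
                    "chrom": cfg.chrom,
                    "start": s0,
                    "end": s0 + ml,
                    "strand": strand,
                    "anchor": site_anchor(s0, s0 + ml, strand),
                    "seq": seq,
                    "motif": which,
                    "peak_index": i,
                    "class": label,
                }
            )
    genome = {cfg.chrom: decode(codes)}
    truth = SyntheticTruth(
        sites=pd.DataFrame(
            site_rows,
            columns=[
                "site_id", "chrom", "start", "end", "strand",
                "anchor", "seq", "motif", "peak_index", "class",
            ],
        ),
        region_classes=pd.DataFrame(class_rows) if class_rows else None,
    )
    return SimData(config=cfg, genome=genome, peaks=peaks, truth=truth)


def simulate_exo_reads(cfg: SimConfig, sim: SimData) -> tuple[list[SimRead], SyntheticTruth]:
    """Emit signal and background reads for a simulated genome.

    Per site, Poisson(reads_per_site) reads each draw a cross-link
    component (mirrored for minus-strand sites) and a stop distance, and
    place their 5' end on the protected strand; reads extend
    ``read_length`` bp 3'-ward, truncated at chromosome ends.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    G = len(sim.genome[cfg.chrom])
    comps = list(cfg.crosslink_offsets)
    weights = np.array([c[2] for c in comps], dtype=float)
    weights /= weights.sum()
    lo, hi = cfg.stop_range
    flip = {"+": "-", "-": "+"}
    reads: list[SimRead] = []
    rows: list[dict] = []

    def emit(five: int, strand: str, name: str):
        if strand == "+":
            start, end = five, min(G, five + cfg.read_length)
        else:
            start, end = max(0, five - cfg.read_length + 1), five + 1
        reads.append(SimRead(cfg.chrom, start, end, strand, 60, name))

    for row in sim.truth.sites.itertuples():
        n = int(rng.poisson(cfg.reads_per_site))
        for j in range(n):
            ci = int(rng.choice(len(comps), p=weights))
            offset, protected, _ = comps[ci]
            d = int(rng.integers(lo, hi + 1))
            if row.strand == "-":
                xl = row.anchor - offset
                prot = flip[protected]
            else:
                xl = row.anchor + offset
                prot = protected
            five = xl - d if prot == "+" else xl + d
            name = f"s{row.site_id}.{j}"
            emit(five, prot, name)
            rows.append(
                {
                    "name": name,
                    "site_id": row.site_id,
                    "offset": offset,
                    "protected": prot,
                    "stop": d,
                    "five_prime": five,
                    "strand": prot,
                }
            )
    n_bg = int(rng.poisson(cfg.background_rate * G))
    for j in range(n_bg):
        five = int(rng.integers(0, G))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"bg.{j}"
        emit(five, strand, name)
        rows.append(
            {
                "name": name,
                "site_id": -1,
                "offset": np.nan,
                "protected": strand,
                "stop": np.nan,
                "five_prime": five,
                "strand": strand,
            }
        )
    truth_reads = pd.DataFrame(
        rows,
        columns=["name", "site_id", "offset", "protected", "stop", "five_prime", "strand"],
    )
    sim.truth.reads = truth_reads
    sim.reads = reads
    return reads, sim.truth


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Genome, peaks, planted sites and reads in one call."""
    sim = simulate_genome_with_sites(cfg)
    simulate_exo_reads(cfg, sim)
    return sim


def mirror_genome(genome: dict[str, str]) -> dict[str, str]:
    """Reverse complement of every chromosome."""
    return {chrom: revcomp(seq) for chrom, seq in genome.items()}
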