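"""Motif models: position weight matrices and degenerate consensus patterns.

A :class:`PositionWeightMatrix` scores sequences by additive log2-odds
against an i.i.d. background. Score thresholds for a requested match
p-value come from the *exact* distribution of the score under the
background model, computed by dynamic programming after discretizing the
per-column log-odds onto a lattice of ``SCORE_GRID`` log2 units. All
scanning code compares scores on that same lattice, so thresholding is
exact with respect to the discretized scores.

A :class:`ConsensusPattern` is an IUPAC string with an explicit set of
*constrained* positions that must match and optional *anti* positions
that must mismatch the consensus preference (the "strike-through" bases
used to dissect degenerate binding sequences).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from .dna import BASES, IUPAC, encode, revcomp

#: Lattice spacing (log2 units) used to discretize per-column log-odds
#: for the exact score-distribution dynamic programme.
SCORE_GRID = 1e-3

#: Floor applied to per-column log-odds before discretization so that a
#: zero probability (possible with pseudocount 0) stays finite.
MIN_LOG_ODDS = -30.0

# Exact score distributions keyed by (background, multiset of lattice
# columns). Column order does not change the distribution of a sum of
# independent per-column scores, so permuted motifs share a cache entry.
_DIST_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed."""


class PositionWeightMatrix:
    """Column-stochastic motif model over {A, C, G, T}.

    Parameters
    ----------
    motif_id:
        Identifier carried through to hits and reports.
    probs:
        Array of shape ``(L, 4)``; columns are normalized to sum to 1.
    background:
        Background base probabilities (length 4, normalized). Defaults
        to the uniform 0.25 model.
    pseudocount:
        The total pseudocount per column that was used to regularize the
        probabilities (informational; smoothing itself happens in
        :meth:`from_counts`).
    """

    def __init__(self, motif_id: str, probs, background=None, pseudocount: float = 0.0):
        probs = np.array(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("probs must be an (L, 4) array with L >= 1")
        if (probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        colsum = probs.sum(axis=1)
        if (colsum <= 0).any():
            raise ValueError("column with zero total probability")
        probs /= colsum[:, None]
        if background is None:
            background = np.full(4, 0.25)
        background = np.array(background, dtype=float)
        if background.shape != (4,) or (background <= 0).any():
            raise ValueError("background must be 4 strictly positive values")
        background /= background.sum()
        self.motif_id = str(motif_id)
        self.probs = probs
        self.background = background
        self.pseudocount = float(pseudocount)

    # -- construction -------------------------------------------------

    @classmethod
    def from_counts(cls, motif_id, counts, background=None, pseudocount: float = 0.01):
        """Build from a count matrix, adding ``pseudocount`` per column.

        The pseudocount is split across bases proportionally to the
        background, then columns are normalized. With the default
        uniform background a pseudocount of 0.01 adds 0.0025 per base.
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        colsum = counts.sum(axis=1)
        if (colsum <= 0).any():
            bad = int(np.nonzero(colsum <= 0)[0][0])
            raise ValueError(f"motif {motif_id!r}: column {bad + 1} has zero total count")
        probs = (counts + pseudocount * bg) / (colsum + pseudocount)[:, None]
        return cls(motif_id, probs, bg, pseudocount)

    # -- basic properties ---------------------------------------------

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length

    @property
    def consensus(self) -> str:
        """Highest-probability base per column (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = self.probs * np.log2(self.probs / self.background)
        return float(np.nansum(terms))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.motif_id, self.probs[::-1, ::-1], self.background, self.pseudocount
        )

    @cached_property
    def log_odds(self) -> np.ndarray:
        """Per-column log2-odds matrix, shape (L, 4); zeros give -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    @cached_property
    def lattice(self) -> np.ndarray:
        """Log-odds floored at MIN_LOG_ODDS and rounded to the score grid."""
        clipped = np.clip(self.log_odds, MIN_LOG_ODDS, None)
        return np.round(clipped / SCORE_GRID).astype(np.int64)

    # -- exact score distribution --------------------------------------

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact (score, probability) arrays under the i.i.d. background.

        Scores are on the discretization lattice, returned in ascending
        order in log2 units; probabilities are the exact background
        probabilities of each attainable lattice score.
        """
        lat, p = self._lattice_distribution()
        return lat.astype(float) * SCORE_GRID, p

    def _lattice_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        lat = self.lattice
        key = self.background.tobytes() + np.array(
            sorted(map(tuple, lat)), dtype=np.int64
        ).tobytes()
        hit = _DIST_CACHE.get(key)
        if hit is not None:
            return hit
        mins = lat.min(axis=1)
        maxs = lat.max(axis=1)
        dist = np.zeros(int((maxs - mins).sum()) + 1)
        dist[0] = 1.0
        cur = 1
        bg = self.background
        for i in range(self.length):
            width = int(maxs[i] - mins[i])
            new = np.zeros(cur + width)
            for b in range(4):
                off = int(lat[i, b] - mins[i])
                new[off : off + cur] += dist[:cur] * bg[b]
            dist = new
            cur += width
        scores = np.arange(dist.size, dtype=np.int64) + int(mins.sum())
        keep = dist > 0
        result = (scores[keep], dist[keep])
        _DIST_CACHE[key] = result
        return result

    def threshold_lattice(self, p: float) -> int:
        """Smallest attainable lattice score whose tail probability <= p.

        If even the maximal score has tail probability above ``p``,
        returns max + 1 (no sequence passes).
        """
        if not 0 < p <= 1:
            raise ValueError("p must be in (0, 1]")
        scores, probs = self._lattice_distribution()
        tail = np.cumsum(probs[::-1])[::-1]
        ok = np.nonzero(tail <= p + 1e-15)[0]
        if ok.size == 0:
            return int(scores[-1]) + 1
        return int(scores[ok[0]])

    def threshold_for_pvalue(self, p: float) -> float:
        return self.threshold_lattice(p) * SCORE_GRID


# -- module-level operations ------------------------------------------


def log_odds_score(pwm: PositionWeightMatrix, seq: str) -> float:
    """Log2-odds score of ``seq`` (length L, A/C/G/T only) under ``pwm``."""
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != motif length {pwm.length}")
    codes = encode(seq)
    if (codes >= 4).any():
        raise ValueError(f"non-ACGT symbol in sequence {seq!r}")
    return float(pwm.log_odds[np.arange(pwm.length), codes].sum())


def threshold_for_pvalue(pwm: PositionWeightMatrix, p: float) -> float:
    """Score threshold with exact background tail probability <= p."""
    return pwm.threshold_for_pvalue(p)


def permute_columns(pwm: PositionWeightMatrix, seed: int) -> PositionWeightMatrix:
    """Shuffle motif columns into a random non-identity order.

    The permutation is drawn uniformly from all permutations and
    resampled if it is the identity: an unshuffled control is not a
    control. Deterministic given ``seed``.
    """
    if pwm.length < 2:
        raise ValueError("need at least 2 columns to permute")
    rng = np.random.default_rng(seed)
    identity = np.arange(pwm.length)
    while True:
        perm = rng.permutation(pwm.length)
        if not np.array_equal(perm, identity):
            break
    return PositionWeightMatrix(
        pwm.motif_id + "_perm", pwm.probs[perm], pwm.background, pwm.pseudocount
    )


def pwm_from_consensus(
    consensus: str,
    strength: float = 0.85,
    motif_id: str = "consensus",
    background=None,
) -> PositionWeightMatrix:
    """Soft PWM from an IUPAC consensus.

    Bases admitted by the code at a position share ``strength`` of the
    probability mass; the rest is split among the other bases. ``N``
    columns are uniform.
    """
    probs = np.empty((len(consensus), 4))
    for i, ch in enumerate(consensus.upper()):
        try:
            allowed = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in consensus") from None
        if len(allowed) == 4:
            probs[i] = 0.25
            continue
        inside = strength / len(allowed)
        outside = (1.0 - strength) / (4 - len(allowed))
        for b, base in enumerate(BASES):
            probs[i, b] = inside if base in allowed else outside
    return PositionWeightMatrix(motif_id, probs, background)


# -- consensus patterns ------------------------------------------------


@dataclass(frozen=True)
class ConsensusPattern:
    """IUPAC pattern with constrained and anti ("strike-through") positions.

    ``constrained`` positions (1-based) must match the code;
    ``anti_positions`` must carry any base *except* one matching the
    code. Positions in neither set are unconstrained regardless of the
    code written there.
    """

    pattern: str
    constrained: frozenset[int] = field(default_factory=frozenset)
    anti_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "pattern", self.pattern.upper())
        object.__setattr__(self, "constrained", frozenset(self.constrained))
        object.__setattr__(self, "anti_positions", frozenset(self.anti_positions))
        if len(self.pattern) < 1:
            raise ValueError("pattern must be non-empty")
        bad = [ch for ch in self.pattern if ch not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad!r} in pattern")
        if self.constrained & self.anti_positions:
            raise ValueError("constrained and anti_positions must be disjoint")
        for pos in self.constrained | self.anti_positions:
            if not 1 <= pos <= len(self.pattern):
                raise ValueError(f"position {pos} outside pattern of length {len(self.pattern)}")
            if self.pattern[pos - 1] == "N":
                raise ValueError(f"position {pos} carries the unconstrained code 'N'")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def matches(self, seq: str) -> bool:
        """True iff ``seq`` satisfies every constrained and anti position."""
        if len(seq) != len(self.pattern):
            raise ValueError(
                f"sequence length {len(seq)} != pattern length {len(self.pattern)}"
            )
        s = seq.upper()
        for pos in self.constrained:
            if s[pos - 1] not in IUPAC[self.pattern[pos - 1]]:
                return False
        for pos in self.anti_positions:
            if s[pos - 1] in IUPAC[self.pattern[pos - 1]]:
                return False
        return True

    def reverse_complement(self) -> "ConsensusPattern":
        L = len(self.pattern)
        return ConsensusPattern(
            revcomp(self.pattern),
            frozenset(L + 1 - p for p in self.constrained),
            frozenset(L + 1 - p for p in self.anti_positions),
        )

    def non_n_positions(self) -> frozenset[int]:
        """1-based positions carrying a code other than N."""
        return frozenset(i + 1 for i, ch in enumerate(self.pattern) if ch != "N")


def match_consensus(pattern: ConsensusPattern, seq: str) -> bool:
    """Functional form of :meth:`ConsensusPattern.matches`."""
    return pattern.matches(seq)


# -- motif file parsing ------------------------------------------------

_JASPAR_ROW = re.compile(
    r"^\s*([ACGTacgt])?\s*[:|]?\s*\[?\s*([0-9.eE+\-\s]*?)\s*\]?\s*$"
)


def load_motifs(
    path,
    format: str = "jaspar",
    background=None,
    pseudocount: float = 0.01,
) -> list[PositionWeightMatrix]:
    """Load PWMs from a JASPAR (2014 4-row) or TRANSFAC matrix file.

    Counts are converted to probabilities column-wise with the given
    pseudocount split by background frequency.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "jaspar":
        records = _parse_jaspar(lines, path)
    elif format == "transfac":
        records = _parse_transfac(lines, path)
    else:
        raise ValueError(f"unknown motif format {format!r} (use 'jaspar' or 'transfac')")
    return [
        PositionWeightMatrix.from_counts(mid, counts, background, pseudocount)
        for mid, counts in records
    ]


def _parse_jaspar(lines, path):
    records = []
    header = None
    rows: list[tuple[str | None, list[float]]] = []

    def flush(lineno):
        if header is None and not rows:
            return
        if header is None:
            raise MotifParseError(f"{path}:{lineno}: matrix rows before any '>' header")
        if len(rows) != 4:
            raise MotifParseError(
                f"{path}:{lineno}: motif {header!r} has {len(rows)} rows, expected 4"
            )
        by_base = {}
        for i, (base, vals) in enumerate(rows):
            by_base[base if base else BASES[i]] = vals
        if set(by_base) != set(BASES):
            raise MotifParseError(f"{path}:{lineno}: motif {header!r} rows are not A/C/G/T")
        lens = {len(v) for v in by_base.values()}
        if len(lens) != 1 or lens == {0}:
            raise MotifParseError(f"{path}:{lineno}: motif {header!r} rows have unequal lengths")
        counts = np.array([by_base[b] for b in BASES]).T
        records.append((header, counts))

    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            rows = []
            header = line[1:].split()[0] if line[1:].split() else f"motif{len(records) + 1}"
            continue
        m = _JASPAR_ROW.match(line)
        if not m:
            raise MotifParseError(f"{path}:{lineno}: cannot parse matrix row {line!r}")
        base, body = m.group(1), m.group(2)
        try:
            vals = [float(x) for x in body.split()]
        except ValueError:
            raise MotifParseError(f"{path}:{lineno}: non-numeric count in row {line!r}") from None
        if not vals:
            raise MotifParseError(f"{path}:{lineno}: empty matrix row {line!r}")
        rows.append((base.upper() if base else None, vals))
    flush(len(lines))
    return records


def _parse_transfac(lines, path):
    records = []
    motif_id = None
    accession = None
    columns: list[list[float]] | None = None
    col_order: list[str] = []

    def flush(lineno):
        nonlocal motif_id, accession, columns, col_order
        if columns is not None:
            if not columns:
                raise MotifParseError(f"{path}:{lineno}: empty TRANSFAC matrix block")
            name = motif_id or accession or f"motif{len(records) + 1}"
            idx = [col_order.index(b) for b in BASES]
            counts = np.array(columns)[:, idx]
            records.append((name, counts))
        motif_id = accession = None
        columns = None
        col_order = []

    in_matrix = False
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split()[0]
        if tag == "AC":
            accession = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else None
        elif tag == "ID":
            motif_id = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else None
        elif tag == "P0" or tag == "PO":
            col_order = [t.upper() for t in line.split()[1:5]]
            if sorted(col_order) != sorted(BASES):
                raise MotifParseError(f"{path}:{lineno}: P0 header is not A C G T")
            columns = []
            in_matrix = True
        elif in_matrix and re.match(r"^\d+$", tag):
            vals = line.split()[1:5]
            if len(vals) != 4:
                raise MotifParseError(f"{path}:{lineno}: matrix row has {len(vals)} values, expected 4")
            try:
                columns.append([float(v) for v in vals])
            except ValueError:
                raise MotifParseError(f"{path}:{lineno}: non-numeric count in row {line!r}") from None
        elif tag in ("XX",):
            in_matrix = False
        elif tag == "//":
            in_matrix = False
            flush(lineno)
    if columns is not None:
        flush(len(lines))
    return records
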