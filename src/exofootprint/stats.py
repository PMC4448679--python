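"""Permuted-motif controls, coverage enrichment tests, and profile algebra.

The null model for "is the 5' coverage around matches of this motif
enriched?" is built by shuffling the motif's columns: a permuted motif
has the same information content and composition but anchors windows at
unrelated positions. Each permuted motif is rescanned with the same
match p-value procedure, its footprint profile is normalized per matched
site, and the observed normalized coverage total is compared against the
permutation distribution with the add-one empirical p-value
``(1 + #{null >= observed}) / (1 + n_perm)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import (
    FivePrimeIndex,
    FootprintProfile,
    ProfileMatrix,
    aggregate_footprint,
    profile_positions,
    site_coverage_matrix,
)
from .motifs import PositionWeightMatrix, permute_columns
from .scan import scan_regions

logger = logging.getLogger(__name__)


@dataclass
class PermutationEnvelope:
    """Position-wise median and interquartile range of permuted profiles.

    Summaries are over per-site-normalized profiles (mean coverage per
    site per position) of ``n_perm`` permuted-motif scans.
    """

    positions: np.ndarray
    forward_q1: np.ndarray
    forward_median: np.ndarray
    forward_q3: np.ndarray
    reverse_q1: np.ndarray
    reverse_median: np.ndarray
    reverse_q3: np.ndarray
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "forward_q1": self.forward_q1,
                "forward_median": self.forward_median,
                "forward_q3": self.forward_q3,
                "reverse_q1": self.reverse_q1,
                "reverse_median": self.reverse_median,
                "reverse_q3": self.reverse_q3,
            }
        )


@dataclass
class CoverageTest:
    """Observed vs permuted-motif normalized coverage for one motif."""

    motif_id: str
    n_sites: int
    observed: float
    null_values: np.ndarray
    p_value: float
    enrichment: float


def _perm_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def permuted_null_profiles(
    genome,
    regions,
    index: FivePrimeIndex,
    pwm: PositionWeightMatrix,
    p: float,
    flank: int,
    n_perm: int,
    seed: int = 0,
) -> list[FootprintProfile]:
    """Footprint profiles of ``n_perm`` seeded column permutations.

    A permutation with zero matches contributes an all-zero profile
    (flagged in the log) so the permutation count stays exact.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    positions = profile_positions(pwm.length, flank)
    profiles: list[FootprintProfile] = []
    for s in _perm_seeds(seed, n_perm):
        permuted = permute_columns(pwm, int(s))
        hits = scan_regions(genome, regions, permuted, p)
        if hits:
            profiles.append(aggregate_footprint(site_coverage_matrix(index, hits, flank)))
        else:
            logger.warning(
                "permutation of %s (seed %d) matched no sites; contributing a zero profile",
                pwm.motif_id,
                int(s),
            )
            zero = np.zeros(positions.size)
            profiles.append(FootprintProfile(positions.copy(), zero.copy(), zero.copy(), 0))
    return profiles


def permutation_envelope(
    genome,
    regions,
    index: FivePrimeIndex,
    pwm: PositionWeightMatrix,
    p: float,
    flank: int,
    n_perm: int = 50,
    seed: int = 0,
    null_profiles: Sequence[FootprintProfile] | None = None,
) -> PermutationEnvelope:
    """Median/IQR envelope of per-site-normalized permuted profiles."""
    if null_profiles is None:
        null_profiles = permuted_null_profiles(
            genome, regions, index, pwm, p, flank, n_perm, seed
        )
    fwd = np.stack([pr.normalized()[0] for pr in null_profiles])
    rev = np.stack([pr.normalized()[1] for pr in null_profiles])
    fq1, fmed, fq3 = np.percentile(fwd, [25, 50, 75], axis=0)
    rq1, rmed, rq3 = np.percentile(rev, [25, 50, 75], axis=0)
    return PermutationEnvelope(
        positions=null_profiles[0].positions.copy(),
        forward_q1=fq1,
        forward_median=fmed,
        forward_q3=fq3,
        reverse_q1=rq1,
        reverse_median=rmed,
        reverse_q3=rq3,
        n_perm=len(null_profiles),
    )


def coverage_pvalue(
    observed: FootprintProfile,
    null_profiles: Sequence[FootprintProfile],
    motif_id: str = "",
) -> CoverageTest:
    """Empirical enrichment test of observed vs permuted coverage.

    The statistic is the whole-window, both-strand normalized coverage
    total. The add-one estimator keeps p in (0, 1].
    """
    if len(null_profiles) == 0:
        raise ValueError("need at least one permuted profile")
    if not np.array_equal(observed.positions, null_profiles[0].positions):
        raise ValueError("observed and null profiles have different position axes")
    obs = observed.normalized_total()
    nulls = np.array([pr.normalized_total() for pr in null_profiles])
    n_perm = nulls.size
    p_value = (1 + int((nulls >= obs).sum())) / (1 + n_perm)
    med = float(np.median(nulls))
    enrichment = obs / med if med > 0 else float("inf") if obs > 0 else float("nan")
    return CoverageTest(
        motif_id=motif_id or "observed",
        n_sites=observed.n_sites,
        observed=obs,
        null_values=nulls,
        p_value=p_value,
        enrichment=enrichment,
    )


def coherence(profile: FootprintProfile) -> bool:
    """True iff the forward maximum lies strictly upstream of the reverse one.

    A protected bound region shows forward-strand 5' density upstream of
    reverse-strand density; this flag screens profiles for that
    peak-pair geometry.
    """
    pf = profile.positions[int(np.argmax(profile.forward))]
    pr = profile.positions[int(np.argmax(profile.reverse))]
    return bool(pf < pr)


def rank_motifs(
    genome,
    regions,
    index: FivePrimeIndex,
    motifs: Sequence[PositionWeightMatrix],
    p: float = 1e-4,
    flank: int = 30,
    n_perm: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage-enrichment ranking of a motif library.

    One test per motif, sorted by ascending p-value then descending
    enrichment; motifs without matches sort last and are flagged.
    Columns: motif_id, n_sites, observed, enrichment, p_value,
    coherence, note.
    """
    if len(motifs) == 0:
        raise ValueError("motif library must be non-empty")
    children = np.random.SeedSequence(seed).spawn(len(motifs))
    rows = []
    for pwm, child in zip(motifs, children):
        child_seed = int(child.generate_state(1)[0])
        hits = scan_regions(genome, regions, pwm, p)
        if not hits:
            rows.append(
                {
                    "motif_id": pwm.motif_id,
                    "n_sites": 0,
                    "observed": 0.0,
                    "enrichment": np.nan,
                    "p_value": np.nan,
                    "coherence": False,
                    "note": "no_match",
                }
            )
            continue
        matrix = site_coverage_matrix(index, hits, flank)
        profile = aggregate_footprint(matrix)
        nulls = permuted_null_profiles(
            genome, regions, index, pwm, p, flank, n_perm, child_seed
        )
        test = coverage_pvalue(profile, nulls, motif_id=pwm.motif_id)
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "n_sites": test.n_sites,
                "observed": test.observed,
                "enrichment": test.enrichment,
                "p_value": test.p_value,
                "coherence": coherence(profile),
                "note": "",
            }
        )
    df = pd.DataFrame(rows)
    df["enr_rank"] = -df["enrichment"].fillna(-np.inf)
    df = (
        df.sort_values(["p_value", "enr_rank"], na_position="last", kind="mergesort")
        .drop(columns="enr_rank")
        .reset_index(drop=True)
    )
    return df


def subsample_profile(matrix: ProfileMatrix, n: int, seed: int = 0) -> FootprintProfile:
    """Footprint of a uniform without-replacement subsample of sites."""
    if not 1 <= n <= matrix.n_sites:
        raise ValueError(f"n must be in [1, {matrix.n_sites}], got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(matrix.n_sites, size=n, replace=False)
    return aggregate_footprint(matrix.subset(idx))


@dataclass
class ProfileDifference:
    """Per-position, per-strand difference of per-site-normalized profiles."""

    positions: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "forward": self.forward, "reverse": self.reverse}
        )


def profile_difference(a: FootprintProfile, b: FootprintProfile) -> ProfileDifference:
    """Difference a - b of profiles normalized by their own site counts."""
    if not np.array_equal(a.positions, b.positions):
        raise ValueError("profiles have different position axes")
    af, ar = a.normalized()
    bf, br = b.normalized()
    return ProfileDifference(a.positions.copy(), af - bf, ar - br)
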