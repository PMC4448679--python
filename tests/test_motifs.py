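"""Motif model: parsing, scoring, exact p-value thresholds, permutation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exofootprint import (
    ConsensusPattern,
    PositionWeightMatrix,
    load_motifs,
    log_odds_score,
    match_consensus,
    permute_columns,
    threshold_for_pvalue,
)
from exofootprint.motifs import MotifParseError, SCORE_GRID

from conftest import random_sequence

JASPAR_TOY = """\
>toy1
A [ 4 0 ]
C [ 0 4 ]
G [ 0 0 ]
T [ 0 0 ]
>toy2 plain-rows
4 0 1
0 4 1
0 0 1
0 0 1
"""

TRANSFAC_TOY = """\
AC M0001
XX
ID toyTF
XX
P0 A C G T
01 4 0 0 0
02 0 4 0 0
03 1 1 1 1
XX
//
"""


# ---------------------------------------------------------------- parsing

def test_jaspar_counts_normalize_without_pseudocount(tmp_path):
    f = tmp_path / "m.jaspar"
    f.write_text(JASPAR_TOY)
    m1, m2 = load_motifs(f, pseudocount=0.0)
    assert m1.motif_id == "toy1" and m1.length == 2
    np.testing.assert_allclose(m1.probs[0], [1, 0, 0, 0])
    np.testing.assert_allclose(m1.probs[1], [0, 1, 0, 0])
    assert m2.length == 3
    np.testing.assert_allclose(m2.probs[2], [0.25] * 4)


def test_jaspar_pseudocount_split_by_background(tmp_path):
    f = tmp_path / "m.jaspar"
    f.write_text(JASPAR_TOY)
    (m1, _) = load_motifs(f, pseudocount=0.01)
    # 0.01 total per column, 0.0025 per base under the uniform background
    assert (m1.probs > 0).all()
    np.testing.assert_allclose(m1.probs[0, 0], 4.0025 / 4.01)
    np.testing.assert_allclose(m1.probs[0, 1], 0.0025 / 4.01)


def test_transfac_parse(tmp_path):
    f = tmp_path / "m.transfac"
    f.write_text(TRANSFAC_TOY)
    (m,) = load_motifs(f, format="transfac", pseudocount=0.0)
    assert m.motif_id == "toyTF" and m.length == 3
    np.testing.assert_allclose(m.probs[1], [0, 1, 0, 0])


@pytest.mark.parametrize(
    "text",
    [
        ">only3rows\nA [ 1 ]\nC [ 1 ]\nG [ 1 ]\n",  # missing a row
        ">bad\nA [ 1 x ]\nC [ 1 1 ]\nG [ 1 1 ]\nT [ 1 1 ]\n",  # non-numeric
    ],
)
def test_jaspar_malformed_block_names_location(tmp_path, text):
    f = tmp_path / "bad.jaspar"
    f.write_text(text)
    with pytest.raises(MotifParseError) as exc:
        load_motifs(f)
    assert "bad.jaspar" in str(exc.value)


def test_zero_count_column_rejected(tmp_path):
    f = tmp_path / "z.jaspar"
    f.write_text(">z\nA [ 1 0 ]\nC [ 1 0 ]\nG [ 1 0 ]\nT [ 1 0 ]\n")
    with pytest.raises(ValueError, match="zero total count"):
        load_motifs(f)


# ---------------------------------------------------------------- scoring

def test_log_odds_matches_independent_enumeration(random_pwm):
    """Every length-5 sequence scores the sum of per-column log-ratios."""
    probs = random_pwm.probs
    for codes in itertools.product(range(4), repeat=5):
        seq = "".join("ACGT"[c] for c in codes)
        expected = sum(math.log2(probs[i][c] / 0.25) for i, c in enumerate(codes))
        assert log_odds_score(random_pwm, seq) == pytest.approx(expected)


def test_consensus_scores_at_least_every_other_sequence(random_pwm):
    best = log_odds_score(random_pwm, random_pwm.consensus)
    for codes in itertools.product(range(4), repeat=5):
        seq = "".join("ACGT"[c] for c in codes)
        assert log_odds_score(random_pwm, seq) <= best + 1e-12


def test_log_odds_input_validation(random_pwm):
    with pytest.raises(ValueError, match="length"):
        log_odds_score(random_pwm, "ACGT")
    with pytest.raises(ValueError, match="non-ACGT"):
        log_odds_score(random_pwm, "ACGTN")


# ----------------------------------------------------------- thresholds

def _enumerated_tail(pwm, lattice_threshold):
    """Background-weighted mass of sequences at/above a lattice score."""
    L = pwm.length
    lat = pwm.lattice
    bg = pwm.background
    mass = 0.0
    for codes in itertools.product(range(4), repeat=L):
        s = sum(int(lat[i, c]) for i, c in enumerate(codes))
        if s >= lattice_threshold:
            mass += math.prod(bg[c] for c in codes)
    return mass


@pytest.mark.parametrize("p", [1e-2, 5e-2, 0.2])
def test_threshold_tail_vs_enumeration_L3(rng, p):
    pwm = PositionWeightMatrix("L3", rng.dirichlet(np.ones(4) * 2, size=3))
    t = pwm.threshold_lattice(p)
    assert _enumerated_tail(pwm, t) <= p + 1e-12
    # the next lower attainable score would exceed p
    scores, _ = pwm._lattice_distribution()
    lower = scores[scores < t]
    if lower.size:
        assert _enumerated_tail(pwm, int(lower[-1])) > p


def test_dp_distribution_equals_enumeration_L6(rng):
    pwm = PositionWeightMatrix("L6", rng.dirichlet(np.ones(4), size=6))
    scores, probs = pwm._lattice_distribution()
    enum = {}
    for codes in itertools.product(range(4), repeat=6):
        s = sum(int(pwm.lattice[i, c]) for i, c in enumerate(codes))
        enum[s] = enum.get(s, 0.0) + math.prod(pwm.background[c] for c in codes)
    assert sorted(enum) == list(scores)
    np.testing.assert_allclose(probs, [enum[s] for s in scores], rtol=1e-12, atol=1e-15)


def test_threshold_p1_is_minimum_attainable_score(random_pwm):
    scores, _ = random_pwm._lattice_distribution()
    assert random_pwm.threshold_lattice(1.0) == scores[0]


@pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
def test_threshold_rejects_invalid_p(random_pwm, p):
    with pytest.raises(ValueError):
        threshold_for_pvalue(random_pwm, p)


def test_gbs_threshold_ladder_monotone():
    from exofootprint import gbs_pwm

    pwm = gbs_pwm()
    ladder = [threshold_for_pvalue(pwm, p) for p in (1e-5, 1e-4, 1e-3, 5e-3)]
    assert all(a >= b for a, b in zip(ladder, ladder[1:]))


def test_empirical_tail_calibration_small(rng):
    """Fraction of background sequences above the p=0.01 threshold is ~0.01."""
    pwm = PositionWeightMatrix("cal", rng.dirichlet(np.ones(4), size=6))
    t = pwm.threshold_lattice(0.01)
    n = 40_000
    codes = rng.integers(0, 4, size=(n, 6))
    scores = pwm.lattice[np.arange(6), codes].sum(axis=1)
    frac = float((scores >= t).mean())
    sd = math.sqrt(0.01 * 0.99 / n)
    assert abs(frac - 0.01) < 3 * sd


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 4))
def test_threshold_tail_property_small_motifs(seed, L):
    """DP threshold obeys its tail-mass contract on random small motifs."""
    rng = np.random.default_rng(seed)
    pwm = PositionWeightMatrix("h", rng.dirichlet(np.ones(4), size=L))
    p = float(rng.uniform(0.001, 0.5))
    t = pwm.threshold_lattice(p)
    assert _enumerated_tail(pwm, t) <= p + 1e-12


# ---------------------------------------------------------- permutation

def test_permute_columns_properties(random_pwm):
    out = permute_columns(random_pwm, seed=7)
    again = permute_columns(random_pwm, seed=7)
    np.testing.assert_array_equal(out.probs, again.probs)  # reproducible
    assert not np.array_equal(out.probs, random_pwm.probs)  # never identity
    got = sorted(map(tuple, out.probs))
    want = sorted(map(tuple, random_pwm.probs))
    assert got == want  # multiset of columns preserved
    assert out.information_content() == pytest.approx(random_pwm.information_content())
    np.testing.assert_array_equal(out.background, random_pwm.background)


def test_permute_length2_always_swaps(rng):
    pwm = PositionWeightMatrix("L2", rng.dirichlet(np.ones(4), size=2))
    for seed in range(100):
        out = permute_columns(pwm, seed)
        np.testing.assert_array_equal(out.probs, pwm.probs[::-1])


def test_permute_length3_uniform_over_non_identity(rng):
    pwm = PositionWeightMatrix("L3", rng.dirichlet(np.ones(4), size=3))
    cols = {tuple(np.round(c, 12)): i for i, c in enumerate(pwm.probs)}
    counts = {}
    n = 3000
    for seed in range(n):
        out = permute_columns(pwm, seed)
        perm = tuple(cols[tuple(np.round(c, 12))] for c in out.probs)
        counts[perm] = counts.get(perm, 0) + 1
    assert (0, 1, 2) not in counts
    assert len(counts) == 5
    for c in counts.values():
        # each of the 5 non-identity permutations ~ n/5, +-4 binomial SD
        assert abs(c - n / 5) < 4 * math.sqrt(n * 0.2 * 0.8)


def test_permute_requires_two_columns():
    pwm = PositionWeightMatrix("L1", [[0.7, 0.1, 0.1, 0.1]])
    with pytest.raises(ValueError):
        permute_columns(pwm, 0)


# ------------------------------------------------------------- consensus

GBS = "NGNACANNNTGTNCN"
GBS_POS = frozenset({2, 4, 5, 6, 10, 11, 12, 14})


def test_match_consensus_fully_constrained():
    pat = ConsensusPattern(GBS, GBS_POS)
    assert match_consensus(pat, "AGTACATTTTGTACA")
    assert not match_consensus(pat, "AGTAAATTTTGTACA")  # A at position 5


def test_match_consensus_anti_position():
    pat = ConsensusPattern(GBS, GBS_POS - {5}, frozenset({5}))
    assert match_consensus(pat, "AGTAAATTTTGTACA")  # pos 5 mismatches C: required
    assert not match_consensus(pat, "AGTACATTTTGTACA")  # consensus C is banned


def test_match_consensus_degenerate_codes():
    pat = ConsensusPattern("RNT", frozenset({1, 3}))
    assert pat.matches("AAT") and pat.matches("GCT")
    assert not pat.matches("CAT")


def test_match_consensus_length_mismatch():
    pat = ConsensusPattern(GBS, GBS_POS)
    with pytest.raises(ValueError):
        match_consensus(pat, "ACGT")


def test_pattern_validation():
    with pytest.raises(ValueError):  # overlap of constrained and anti
        ConsensusPattern("ACG", frozenset({1}), frozenset({1}))
    with pytest.raises(ValueError):  # N cannot be constrained
        ConsensusPattern("ANG", frozenset({2}))
    with pytest.raises(ValueError):  # out of range
        ConsensusPattern("ACG", frozenset({4}))


def test_pattern_reverse_complement_roundtrip():
    pat = ConsensusPattern(GBS, GBS_POS - {5}, frozenset({5}))
    rc = pat.reverse_complement()
    assert rc.pattern == GBS  # the GBS consensus is its own reverse complement
    assert rc.reverse_complement() == pat
    seq = "AGTACATTTTGTACA"
    from exofootprint import revcomp

    assert pat.matches(seq) == rc.matches(revcomp(seq))
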