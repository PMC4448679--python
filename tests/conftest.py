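import numpy as np
import pytest

from exofootprint import PositionWeightMatrix, pwm_from_consensus


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_pwm(rng):
    """A moderately informative random length-5 motif."""
    return PositionWeightMatrix("rand5", rng.dirichlet(np.ones(4), size=5))


@pytest.fixture
def sharp_pwm():
    """High-information non-palindromic 10-mer used to plant unambiguous sites."""
    return pwm_from_consensus("ACGGTAATCC", strength=0.91, motif_id="sharp")


def make_genome(seq: str, chrom: str = "chr1") -> dict:
    return {chrom: seq.upper()}


def random_sequence(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
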