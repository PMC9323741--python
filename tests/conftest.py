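import numpy as np
import pytest

from dnaspectra import DnaSequence, periodic_sequence, to_indicators

#: The small worked sequence whose binary indicators are enumerated by hand.
TOY = "CTGATCCTTCAAGCG"
TOY_INDICATORS = {
    "A": "000100000011000",
    "C": "100001100100010",
    "G": "001000000000101",
    "T": "010010011000000",
}


@pytest.fixture
def toy_sequence() -> DnaSequence:
    return DnaSequence(id="toy", symbols=TOY)


@pytest.fixture
def cacccg300():
    """Period-CACCCG sequence, 50 repeats (N=300): 3 bp and 6 bp periodicities."""
    return to_indicators(periodic_sequence("CACCCG", 50))


@pytest.fixture
def acgtgc300():
    """Period-ACGTGC sequence, 50 repeats (N=300)."""
    return to_indicators(periodic_sequence("ACGTGC", 50))


def random_dna(rng: np.random.Generator, n: int) -> DnaSequence:
    symbols = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    return DnaSequence(id=f"rnd{n}", symbols=symbols)


def random_unit_mappings(rng: np.random.Generator, count: int) -> np.ndarray:
    """(count, 4) complex array of unit-norm weight vectors."""
    w = rng.standard_normal((count, 4)) + 1j * rng.standard_normal((count, 4))
    return w / np.linalg.norm(w, axis=1, keepdims=True)
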