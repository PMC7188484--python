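import numpy as np
import pytest

from hoxcomp import GenomicSequence

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, with_n: float = 0.0) -> str:
    chars = BASES + ("N" if with_n else "")
    if with_n:
        probs = [(1 - with_n) / 4] * 4 + [with_n]
        return "".join(rng.choice(list(chars), size=length, p=probs))
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def make_seq():
    def _make(residues: str, sid: str = "s1", species: str = "") -> GenomicSequence:
        return GenomicSequence(sid, residues, species=species)

    return _make
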