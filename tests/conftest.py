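import numpy as np
import pytest

from promscan.io import SequenceRecord
from promscan.motifs import PositionMatrix


@pytest.fixture
def maz_like_matrix() -> PositionMatrix:
    """Near-deterministic 7-column matrix whose consensus is GGGAGGG."""
    counts = np.array(
        [
            [0, 1, 0, 17, 1, 0, 0],
            [1, 0, 1, 1, 0, 1, 2],
            [18, 18, 18, 1, 18, 18, 17],
            [1, 1, 1, 1, 1, 1, 1],
        ],
        dtype=float,
    )
    return PositionMatrix("MAZ-like", counts)


@pytest.fixture
def elf1_like_matrix() -> PositionMatrix:
    """Matrix with the ETS-family AGGAA core as its consensus."""
    counts = np.array(
        [
            [20, 0, 1, 19, 18],
            [0, 1, 0, 0, 1],
            [0, 18, 19, 0, 0],
            [0, 1, 0, 1, 1],
        ],
        dtype=float,
    )
    return PositionMatrix("ELF1-like", counts)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_record(residues: str, name: str = "test") -> SequenceRecord:
    return SequenceRecord(name, residues)
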