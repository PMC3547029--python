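import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_fasta() -> Path:
    return DATA / "toy.fa"


@pytest.fixture(scope="session")
def rm_out() -> Path:
    return DATA / "toy_repeatmasker.out"


@pytest.fixture(scope="session")
def recomb_map_tsv() -> Path:
    return DATA / "toy_recomb_map.tsv"


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231115)
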