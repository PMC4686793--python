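import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # golden_grammars helper


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_symmetric_matrix(rng, n, low=1.0, high=10.0):
    d = rng.uniform(low, high, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
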