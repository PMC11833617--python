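import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


@pytest.fixture()
def random_peptides():
    """Factory: n random peptides of the given lengths."""

    def make(n, min_len=10, max_len=90, seed=12345):
        r = np.random.default_rng(seed)
        return [
            (f"pep{i:04d}", random_peptide(r, int(r.integers(min_len, max_len + 1))))
            for i in range(n)
        ]

    return make
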