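import numpy as np
import pytest

from aipkit.peptide_io import AMINO_ACIDS, PeptideRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, min_len=1, max_len=25, idx=0) -> PeptideRecord:
    length = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return PeptideRecord(id=f"r{idx}", sequence=seq)


@pytest.fixture
def random_peptides(rng):
    def make(n, min_len=1, max_len=25):
        return [random_peptide(rng, min_len, max_len, i) for i in range(n)]

    return make
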