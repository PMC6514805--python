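import numpy as np
import pytest

from acpmeta.seqio import Peptide, PeptideSet
from acpmeta.tables import AA_ORDER, default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_peptide(rng, lmin=5, lmax=50) -> str:
    length = int(rng.integers(lmin, lmax + 1))
    return "".join(rng.choice(list(AA_ORDER), size=length))


def make_set(seqs, label=None) -> PeptideSet:
    return PeptideSet([Peptide(f"p{i}", s, label) for i, s in enumerate(seqs)])


@pytest.fixture()
def random_set(rng):
    return make_set([random_peptide(rng) for _ in range(12)])
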