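import numpy as np
import pytest

from polymine.io_formats import SequenceRecord
from polymine.synthetic_data import SimulationParams, make_truth

BASES = "ACGT"


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def small_truth():
    """A compact labelled truth set shared by read-only tests."""
    params = SimulationParams(n_genes=12, seed=7)
    return make_truth(params)


@pytest.fixture()
def make_records():
    def _make(seqs, prefix="s"):
        return [SequenceRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)]

    return _make
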