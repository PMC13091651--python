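import numpy as np
import pytest

from rnalink.io import InteractionTable, RnaSequence
from rnalink.synthetic import gen_sequences


@pytest.fixture
def rna(request):
    def make(seq, rna_id="x", rna_type="lncRNA"):
        return RnaSequence(id=rna_id, seq=seq, rna_type=rna_type)
    return make


@pytest.fixture
def random_sequences():
    return gen_sequences(20, (30, 60), "lncRNA", seed=11)


@pytest.fixture
def toy_table():
    pairs = [("l0", "m0", 1), ("l0", "m1", 1), ("l1", "m1", 1),
             ("l1", "m2", 1), ("l2", "m0", 1), ("l2", "m2", 1)]
    return InteractionTable.from_pairs(pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
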