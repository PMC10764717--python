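import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ksclass.seqio import ProteinSequence
from ksclass.synthetic import FamilySpec, make_family_hmm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_family():
    """A small conserved family model shared across tests."""
    return make_family_hmm(FamilySpec("toyfam", M=30, conservation=0.8,
                                      indel_rate=0.02, seed=5))


def random_protein(rng, n, seq_id="q"):
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    return ProteinSequence(id=seq_id, residues="".join(rng.choice(letters, size=n)))
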