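import numpy as np
import pytest

from aluscan.models import ReferenceGenome, SequenceRecord
from aluscan.synthetic import make_consensus_library, make_reference


@pytest.fixture(scope="session")
def library():
    return make_consensus_library()


@pytest.fixture(scope="session")
def small_reference():
    """120 kb random genome, no repeats."""
    ref, _, _ = make_reference(3, 120_000, 0)
    return ref


@pytest.fixture(scope="session")
def annotated_reference():
    """300 kb genome with 12 planted fixed Alus (half excisable AluYs)."""
    ref, ann, lib = make_reference(11, 300_000, 12)
    return ref, ann, lib


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_genome(seq, name="chr1"):
    return ReferenceGenome([SequenceRecord(name, seq)])
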