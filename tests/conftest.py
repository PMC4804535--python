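import numpy as np
import pytest

from mawdist import AB, DNA, SeqRecord


@pytest.fixture
def abbaab():
    return SeqRecord("x", ("abbaab",), AB)


@pytest.fixture
def aab():
    return SeqRecord("y", ("aab",), AB)


@pytest.fixture
def rng():
    return np.random.default_rng(20160322)


def random_dna(rng, length):
    return "".join(rng.choice(list(DNA.symbols), size=length))
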