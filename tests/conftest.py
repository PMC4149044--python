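import numpy as np
import pytest

from cpgdesert.intervals import SequenceRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240820)


def random_sequence(rng, length, p=(0.3, 0.2, 0.2, 0.3)):
    codes = rng.choice(4, size=length, p=list(p))
    return BASES[codes].tobytes().decode("ascii")


@pytest.fixture
def random_record(rng):
    return SequenceRecord("chrR", random_sequence(rng, 2000))
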