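import numpy as np
import pytest
from hypothesis import settings

from fpcompare import BinaryFingerprint, generate_library, similarity_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20150520)


@pytest.fixture(scope="session")
def druglike_library():
    """A homogeneous dense library of 100 molecules."""
    return generate_library(100, "druglike", 1024, "dense", seed=7)


@pytest.fixture(scope="session")
def druglike_table(druglike_library):
    """Similarity table of 99 molecules against the first as reference."""
    ref, *rest = druglike_library
    return similarity_table(ref, rest)


def random_fingerprint(rng, length=64, density=0.3, id="fp"):
    k = rng.binomial(length, density)
    bits = rng.choice(length, size=k, replace=False)
    return BinaryFingerprint(id=id, length=length,
                             on_bits=frozenset(int(b) for b in bits))
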