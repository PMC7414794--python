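import numpy as np
import pytest

import chemokit as ck


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def family_200():
    """One study-like synthetic family shared by classifier/signal tests."""
    spec = ck.SimSpec(seed=2024, n=200)
    genes, proteins, truth = ck.gen_family(spec)
    return genes, proteins, truth
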