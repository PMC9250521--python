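import numpy as np
import pytest

from nvdt.seqio import GeneSequence
from nvdt import synthetic


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def aata():
    return GeneSequence("x", "AATA")


@pytest.fixture(scope="session")
def small_dataset():
    """A small strongly-separable synthetic dataset shared across tests."""
    cfg = synthetic.SyntheticConfig(n_pairs=20, seq_len_nt=300, effect=1.0,
                                    n_profiles=2, seed=7)
    return synthetic.generate_dataset(cfg)
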