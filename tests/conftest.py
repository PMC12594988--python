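import numpy as np
import pytest

from motifbench.motifs import FrequencyMatrix, pfm_to_pwm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_freqs(rng):
    def make(length: int, concentration: float = 1.0) -> FrequencyMatrix:
        return FrequencyMatrix(rng.dirichlet(np.full(4, concentration), size=length))

    return make


@pytest.fixture
def random_weights(random_freqs):
    def make(length: int, concentration: float = 1.0):
        return pfm_to_pwm(random_freqs(length, concentration), 100)

    return make


def random_dna(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
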