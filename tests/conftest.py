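import numpy as np
import pytest

from probparafac2 import FactorSet, SimConfig, SlabTensor, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_factors(rng) -> FactorSet:
    """Random shape-consistent factor set: I=5, M=3, K=4, ragged J."""
    M = 3
    J = [6, 4, 7, 5]
    P = [np.linalg.qr(rng.standard_normal((j, M)))[0] for j in J]
    return FactorSet(
        A=rng.standard_normal((5, M)),
        C=rng.uniform(0.5, 2.0, size=(4, M)),
        F=rng.standard_normal((M, M)),
        P=P,
    )


@pytest.fixture
def ragged_tensor(rng) -> SlabTensor:
    return SlabTensor([rng.standard_normal((5, j)) for j in (6, 4, 7, 5)])


@pytest.fixture(scope="session")
def noisy_dataset():
    """A 20x20x6, M=3 synthetic dataset at 4 dB, shared across tests."""
    return simulate(SimConfig(I=20, J=20, K=6, M=3, snr_db=4.0, seed=77))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free 20x20x6, M=3 dataset."""
    return simulate(SimConfig(I=20, J=20, K=6, M=3, snr_db=np.inf, seed=78))
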