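import numpy as np
import pytest

from dyadsync import DyadSimParams, gen_energy_dyad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def one_way_dyad():
    """Strongly one-way-coupled dyad (subject follows actor at 2 s)."""
    de, gt = gen_energy_dyad(DyadSimParams(
        duration=200, coupling_sa=0.8, lag_sa=2.0, seed=7))
    return de, gt


@pytest.fixture(scope="session")
def mutual_dyad():
    """Symmetric bidirectionally coupled dyad."""
    de, gt = gen_energy_dyad(DyadSimParams(
        duration=200, sync_strength=0.6, coupling_sa=0.6, coupling_as=0.6,
        lag_sa=1.5, lag_as=1.5, seed=11))
    return de, gt
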