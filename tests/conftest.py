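import numpy as np
import pytest

from ivivckit import gen_be_dataset, run_twostep


@pytest.fixture(scope="session")
def be_dataset():
    """Noiseless two-study, three-product recovery fixture."""
    return gen_be_dataset(seed=1)


@pytest.fixture(scope="session")
def twostep_result(be_dataset):
    """Full two-step pipeline run on the recovery fixture (shared across tests)."""
    return run_twostep(be_dataset.study1, be_dataset.study2, be_dataset.dissolution)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200706)
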