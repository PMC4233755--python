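import pytest

from biodomain import build_eae_model, run_sim
from biodomain.eae import default_sim_config


@pytest.fixture(scope="session")
def eae_model():
    return build_eae_model()


@pytest.fixture(scope="session")
def baseline_series(eae_model):
    """One default-parameter EAE run, shared by observation-level tests."""
    return run_sim(eae_model, default_sim_config(seed=0))
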