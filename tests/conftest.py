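import pytest

import avbci


@pytest.fixture(scope="session")
def codebook():
    return avbci.build_codebook()


@pytest.fixture(scope="session")
def small_session(codebook):
    """12-character low-noise session shared across pipeline tests."""
    text = avbci.random_text(12, codebook, seed=7)
    cfg = avbci.SimConfig(seed=7, noise_amplitude=1.0)
    return avbci.simulate_session(text, codebook, cfg)


@pytest.fixture(scope="session")
def small_epochs(small_session):
    return avbci.preprocess_pipeline(small_session)
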