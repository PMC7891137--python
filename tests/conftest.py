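import pytest

from lncforge import synthetic as sy


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study (seed 1): 50 PCGs, 210 candidates, 6 samples."""
    return sy.generate_scenario(sy.SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free variant: every planted signal is exactly recoverable."""
    return sy.generate_scenario(sy.SyntheticScenario(seed=11, noise_sd=0.0))
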