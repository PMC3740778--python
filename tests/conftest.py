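import numpy as np
import pytest

from txfactory.synthetic_data import SpreadGenParams, generate_spread_fibres


@pytest.fixture(scope="session")
def default_sample():
    """~10,000 tracks generated at the calibrated default conditions."""
    return generate_spread_fibres(SpreadGenParams(n_clusters=1300, seed=1))


@pytest.fixture(scope="session")
def default_lengths(default_sample):
    return default_sample.track_lengths_kb()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
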