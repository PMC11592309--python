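import numpy as np
import pytest

from wavesleep import (
    StageMarkovSpec,
    decompose,
    extract_night_features,
    simulate_stage_sequence,
    synthesize_night,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_night():
    """A 40-epoch synthetic night with the default stage spectra."""
    labels = simulate_stage_sequence(StageMarkovSpec(n_epochs=40, seed=7))
    return synthesize_night(labels, seed=8, night_id="fixture-night")


@pytest.fixture(scope="session")
def small_night_features(small_night):
    """db4 feature matrix of the fixture night (40 x 105)."""
    return extract_night_features(small_night, wavelet="db4")


@pytest.fixture(scope="session")
def random_epoch(rng):
    return rng.normal(size=3000)


@pytest.fixture(scope="session")
def random_bands(random_epoch):
    return decompose(random_epoch, "db4")
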