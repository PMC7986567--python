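import numpy as np
import pytest

from itsarima import TimeSeries, make_quetiapine_like_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    """The default synthetic dispensing-like 48-month fixture."""
    return make_quetiapine_like_fixture()


@pytest.fixture(scope="session")
def fixture_series(fixture_dataset):
    return fixture_dataset.series


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def white_noise_series(rng):
    return TimeSeries(rng.normal(0.0, 1.0, 400), period=1)
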