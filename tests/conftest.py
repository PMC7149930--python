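import numpy as np
import pytest

from hrnv import RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def physiological_series(rng):
    """A plausible ~6-minute NN series: 800 ms mean, moderate variability."""
    x = rng.normal(800.0, 40.0, 450).clip(400, 1600)
    return RRSeries(x, source_id="synthetic-fixture")


def random_rr(rng, length, mean=800.0, sd=50.0):
    return RRSeries(rng.normal(mean, sd, length).clip(mean * 0.3, mean * 2.5))
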