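import numpy as np
import pytest

from ewsignals import AbundanceSeries, GeneratorConfig, generate_stationary


@pytest.fixture
def years26():
    return np.arange(1987, 2013)


@pytest.fixture
def series26(years26):
    """A fixed 26-point stationary series spanning 1987-2012."""
    return generate_stationary(GeneratorConfig(seed=12345))


@pytest.fixture
def flat_series(years26):
    return AbundanceSeries(years=years26, estimates=np.full(26, 5000.0))
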