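import numpy as np
import pytest

from massphot import InstrumentModel


@pytest.fixture
def instrument():
    """Default instrument: 12 kDa event error, 40 kDa detection floor."""
    return InstrumentModel(
        mass_sigma=12.0,
        detection_limit=40.0,
        contrast_slope=1e-3,
        contrast_intercept=0.0,
        events_expected=5000.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240104)
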