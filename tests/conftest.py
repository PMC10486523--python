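import logging

import numpy as np
import pytest

from immunomri import FieldParams, PhantomSpec


@pytest.fixture(autouse=True)
def _quiet_logs():
    # discordance / exclusion warnings are expected in bulk simulation
    logging.getLogger("immunomri").setLevel(logging.ERROR)
    yield
    logging.getLogger("immunomri").setLevel(logging.NOTSET)


@pytest.fixture
def small_spec():
    """A 24^3 noiseless phantom with gentle parameter gradients."""
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        tumor_radii=(6.0, 7.0, 8.0),
        pe_field=FieldParams(200.0, (0.0, 2.0, 0.0)),
        ser_field=FieldParams(1.5, (0.01, 0.0, 0.0)),
        adc_field=FieldParams(1.0e-3, (0.0, 0.0, 5.0e-6)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
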