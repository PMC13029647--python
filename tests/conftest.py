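import numpy as np
import pytest

from coleach import CascadeParams, SyntheticScenario
from coleach.synth import generate_continuous_cascade


@pytest.fixture
def default_scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture
def cascade_bundle(default_scenario):
    return generate_continuous_cascade(default_scenario)


@pytest.fixture
def toxic_params():
    """Cascade parameters of the net-death regime (mu2 < 0)."""
    return CascadeParams(D=0.2, mu1=0.2, mu2=-1.07, X1_0=200.0, X2_0=200.0)


@pytest.fixture
def dense_times():
    return np.arange(0.0, 30.0 + 1e-9, 0.1)


# Published reference dilution table: (day, printed in-reactor conc, g/L).
PUBLISHED_DILUTION_TABLE = [
    (0, 5.0), (3, 5.0), (5, 5.0), (7, 5.0), (9, 5.0),
    (11, 5.0), (14, 8.0), (16, 9.8), (18, 10.9), (20, 11.5),
    (22, 11.9), (25, 22.2), (27, 28.3), (29, 32.0), (31, 34.2), (34, 35.5),
]
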