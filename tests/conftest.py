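import numpy as np
import pytest

import protorange as pr


@pytest.fixture(scope="session")
def small_water_2d():
    """Small uniform water section for fast solver checks (80 x 80 mm)."""
    return pr.MediumGrid(
        spacing=1.0,
        speed=np.full((80, 80, 1), 1498.0),
        density=np.full((80, 80, 1), 997.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
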