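import numpy as np
import pytest

from ctor import (
    DISPERSIVE,
    LESS_DISPERSIVE,
    SIMPLE_GENERATOR,
    UNIFORM,
    build_trellis,
    validate_channel,
)


@pytest.fixture(scope="session")
def simple_trellis():
    return build_trellis(SIMPLE_GENERATOR)


@pytest.fixture(scope="session")
def identity_channel():
    """Noiseless binary channel: bit n is received as symbol index n."""
    return validate_channel([[1.0, 0.0], [0.0, 1.0]], ("0", "1"))


@pytest.fixture(params=["dispersive", "less_dispersive"])
def dmc(request):
    return {"dispersive": DISPERSIVE, "less_dispersive": LESS_DISPERSIVE}[
        request.param
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# the three 15-bit object representations used throughout (brown bear,
# baby elephant, green hat)
OBJECTS = {
    "b1": [1, 1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 0, 0, 1],
    "b2": [1, 1, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1, 0, 0],
    "b3": [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1],
}


@pytest.fixture(scope="session")
def object_triplet():
    return {k: np.asarray(v, dtype=np.uint8) for k, v in OBJECTS.items()}
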