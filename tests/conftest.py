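import numpy as np
import pytest

from tdoatrack.simulate import default_array


@pytest.fixture
def rng():
    return np.random.default_rng(20160920)


@pytest.fixture(scope="session")
def hex_array():
    """The default seven-receiver layout (centre + regular hexagon)."""
    return default_array()
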