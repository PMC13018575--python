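import numpy as np
import pytest

import carotidseg as cs


@pytest.fixture(scope="session")
def transverse_phantom():
    """Default transverse phantom (seed 0): image, lumen mask, spec."""
    spec = cs.default_transverse_spec(seed=0)
    img, mask = cs.make_phantom(spec)
    return img, mask, spec


@pytest.fixture(scope="session")
def longitudinal_phantom():
    """Default longitudinal phantom with jugular decoy (seed 0)."""
    spec = cs.default_longitudinal_spec(seed=0)
    img, mask = cs.make_phantom(spec)
    return img, mask, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
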