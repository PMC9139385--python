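import numpy as np
import pytest

from biplanar3d import phantom


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale phantom grid matching the scale-1/4 generator output."""
    return phantom.PhantomSpec(grid_shape=(32, 32, 64),
                               spacing_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return phantom.generate_phantom(desk_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
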