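import numpy as np
import pytest

from stromamech import FiberFieldParams, generate_fiber_image


@pytest.fixture(scope="session")
def small_fiber_params():
    """A small, quick-to-render fiber field used across tests."""
    return FiberFieldParams(
        image_size_px=(200, 200),
        n_fibers=30,
        length_um_mean=30.0,
        length_um_sd=5.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_fiber_image(small_fiber_params):
    return generate_fiber_image(small_fiber_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
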