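import numpy as np
import pytest

from radscar.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_spec():
    """A compact phantom that still fits several 25x25 tiles per class."""
    return PhantomSpec(
        image_size=192,
        inner_radius=40.0,
        outer_radius=90.0,
        scar_arcs=((20.0, 110.0),),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)
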