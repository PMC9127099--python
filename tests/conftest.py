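import numpy as np
import pytest

from c2fseg import synthgen


@pytest.fixture(scope="session")
def small_circles():
    """A small seeded circle dataset shared by read-only tests."""
    spec = synthgen.CircleSpec(
        n_images=6, image_size=64, radius_range=(6, 12), circles_per_image=(1, 3), seed=11
    )
    return synthgen.gen_circles(spec)


@pytest.fixture(scope="session")
def small_field():
    spec = synthgen.FieldSpec(n_images=6, image_size=64, seed=7)
    return synthgen.gen_field(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
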