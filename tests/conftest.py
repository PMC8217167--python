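import numpy as np
import pytest

from canopyhist import CanopyImage, generate_cohort, reviving_scenario


def make_image(arr, **meta) -> CanopyImage:
    return CanopyImage(pixels=np.asarray(arr, dtype=np.uint8), **meta)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 90-sample reviving cohort shared by protocol-level tests."""
    return generate_cohort(reviving_scenario(seed=11, image_size=(48, 48)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
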