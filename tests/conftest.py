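import numpy as np
import pytest

from isletmap import IsletSimConfig, StainSimConfig, generate_islet_traces, generate_stain_image

FRAME_RATE = 20.0


@pytest.fixture(scope="session")
def small_islet():
    """A small reference islet recording shared by read-only tests."""
    cfg = IsletSimConfig(n_cells=30, hub_fraction=0.1, duration_s=90.0, seed=11)
    return generate_islet_traces(cfg)


@pytest.fixture(scope="session")
def stain_fixture():
    cfg = StainSimConfig(n_cells=30, seed=5)
    image, truth = generate_stain_image(cfg)
    return image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
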