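import numpy as np
import pytest

from pigpen.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scene():
    """A short low-resolution scene with ground truth, rendered once."""
    spec = SceneSpec(width=128, height=96, n_frames=30, n_animals=2,
                     semi_major_range=(14.0, 18.0), semi_minor_range=(7.0, 9.0),
                     seed=7)
    return spec, list(generate_scene(spec))
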