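import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """One straight-tube scene on a small frame, cheap to segment."""
    from tubequant.simulate import SceneSpec

    return SceneSpec(image_shape=(128, 128), pixel_size=0.1, n_tubes=3,
                     length_distribution={"values": [2.0, 3.0, 4.0]},
                     curvature=0.0, seed=7)


@pytest.fixture
def fast_config():
    from tubequant.segment import PipelineConfig

    return PipelineConfig(median_radius=10, gaussian_sigma=0.5,
                          length_metric="calibrated")
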