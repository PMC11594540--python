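import numpy as np
import pytest

from exmplate import synthim


@pytest.fixture(scope="session")
def circle_stack():
    """Noise-free radially symmetric nucleus, radius 60 px."""
    shape = synthim.make_nucleus_shape(seed=1, base_radius=60, irregularity=0, n_harmonics=0)
    return synthim.render_nucleus_stack(shape, synthim.DEFAULT_PROFILE, n_planes=1)


@pytest.fixture(scope="session")
def multi_nucleus_field():
    """A 400x400 field of several nuclei near the center (content survives
    a ~4x expansion without leaving the frame), at peak SNR ~ 10."""
    rng = np.random.default_rng(7)
    nuclei = []
    for i in range(6):
        cy, cx = 199.5 + rng.uniform(-30, 30, 2)
        sh = synthim.make_nucleus_shape(
            seed=10 + i,
            base_radius=rng.uniform(10, 14),
            irregularity=0.2,
            n_harmonics=4,
            center=(cy, cx),
        )
        nuclei.append((sh, synthim.DEFAULT_PROFILE))
    return synthim.render_field(nuclei, image_shape=(400, 400), noise=(150, 0.02), seed=3)

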