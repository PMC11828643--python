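import numpy as np
import pytest

from floodqc import FloodImage, PhantomSpec


@pytest.fixture
def desk_spec():
    """Fast noisy acquisition profile: 64x64 matrix, 2,000 kilocounts."""
    return PhantomSpec.desk_scale()


@pytest.fixture
def uniform_image():
    """20x20 matrix, uniform 100 inside a centered 16x16 block, 0 outside."""
    counts = np.zeros((20, 20))
    counts[2:18, 2:18] = 100.0
    return FloodImage(counts=counts, pixel_spacing_mm=(6.4, 6.4))
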