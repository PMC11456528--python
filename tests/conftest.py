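import numpy as np
import pytest

from stacknorm import AttenuationModel, PhantomSpec, ZStack, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack(rng):
    """A random 3-section 4x4 8-bit stack."""
    return ZStack(rng.integers(0, 256, size=(3, 4, 4), dtype=np.uint8), bit_depth=8)


@pytest.fixture
def phantom_pair():
    """Default noise-free phantom: 40 sections, 128x128, decay to 30%."""
    spec = PhantomSpec()
    model = AttenuationModel.exponential_to(0.3, spec.shape[0])
    return generate_pair(spec, model)
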