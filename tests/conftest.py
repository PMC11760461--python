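import numpy as np
import pytest

from angiovis import PhantomSpec, generate_phantom, load_config
from angiovis.enhance import enhance_frame


@pytest.fixture(scope="session")
def default_config():
    return load_config()


@pytest.fixture(scope="session")
def default_phantom():
    """One seeded default phantom (256 px), shared across test modules."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def enhanced_phantom(default_phantom):
    """The default phantom pushed through the full pipeline once."""
    frame, gt = default_phantom
    result, diag = enhance_frame(frame)
    return frame, gt, result, diag


@pytest.fixture
def rng():
    return np.random.default_rng(42)
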