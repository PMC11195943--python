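import numpy as np
import pytest

from pskde import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom image + five masks at the default configuration."""
    return generate_phantom(PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def phantom_batch():
    """Ten phantoms at the default configuration, seed 42."""
    cfg = PhantomConfig(seed=42)
    rng = np.random.default_rng(42)
    return [generate_phantom(cfg, rng) for _ in range(10)]


def random_mask_pair(rng, shape=(16, 16)):
    """A random pair of binary masks (may be empty or full)."""
    p1, p2 = rng.uniform(0.05, 0.95, size=2)
    gt = (rng.random(shape) < p1).astype(np.uint8)
    pr = (rng.random(shape) < p2).astype(np.uint8)
    return gt, pr
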