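import numpy as np
import pytest

from spinevc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One clean default-spec phantom shared across read-only tests."""
    spec = PhantomSpec(seed=42)
    image, mask, truth = generate_phantom(spec)
    return spec, image, mask, truth


@pytest.fixture(scope="session")
def compressed_phantom():
    """Phantom with a 30% anterior wedge on vertebra 2."""
    spec = PhantomSpec(compression_map={2: 0.3}, seed=7)
    image, mask, truth = generate_phantom(spec)
    return spec, image, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
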