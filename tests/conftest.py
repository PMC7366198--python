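import numpy as np
import pytest

from mscc import synthetic


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 64x64 scene (ellipse family)."""
    return synthetic.generate_scene(0, 64, seed=7)


@pytest.fixture(scope="session")
def scene_per_family():
    """One scene from each shape family, 48x48."""
    return [synthetic.generate_scene(cid, 48, seed=3) for cid in range(3)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
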