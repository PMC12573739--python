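import numpy as np
import pytest

from pitchcode.montage import delaunay_adjacency, ring_montage


@pytest.fixture(scope="session")
def small_montage():
    """16-electrode ring layout with its Delaunay neighbourhood graph."""
    mont = ring_montage(16)
    return mont, delaunay_adjacency(mont.positions)


@pytest.fixture(scope="session")
def story_10s():
    """Short narrated-speech surrogate shared across F0 tests."""
    from pitchcode.synth import gen_continuous_stimulus

    return gen_continuous_stimulus(10.0, seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
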