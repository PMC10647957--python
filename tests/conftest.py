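import numpy as np
import pytest

from mireg import AffineRanges, PhantomSpec, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair():
    """One tumor-bearing 96x96 multimodal pair with a moderate misalignment."""
    spec = PhantomSpec(size=96, tumor=True, seed=7)
    ranges = AffineRanges(max_translation=6.0, max_rotation_deg=10.0,
                          scale=(0.95, 1.05), max_shear=0.03)
    return make_pair(spec, ranges, seed=7)


@pytest.fixture(scope="session")
def aligned_pair():
    """A perfectly aligned (identity-transform) multimodal pair."""
    spec = PhantomSpec(size=96, tumor=True, seed=3)
    return make_pair(spec, AffineRanges(0.0, 0.0, (1.0, 1.0), 0.0), seed=3)
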