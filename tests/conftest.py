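import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from freqcycle.synthetic import DegradationSpec, PhantomSpec, make_phantom_ct, degrade_to_cbct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A small phantom CT with its label map (session-wide, read-only)."""
    spec = PhantomSpec(shape=(16, 48, 48), spacing=(2.0, 2.0, 3.0),
                      tumor_radius=2.5, seed=42)
    return make_phantom_ct(spec)


@pytest.fixture(scope="session")
def phantom_pair(small_phantom):
    """(CT, CBCT) pair from the small phantom with the default degradation."""
    ct, _ = small_phantom
    return ct, degrade_to_cbct(ct, DegradationSpec(seed=7))
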