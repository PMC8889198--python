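import numpy as np
import pytest

from ifdsim import PatchLandscape, SimState


def make_state(qualities, counts, activity=1.0):
    """Build a SimState with consumers placed to match the given counts."""
    qualities = np.asarray(qualities, dtype=float)
    counts = np.asarray(counts, dtype=int)
    landscape = PatchLandscape.from_qualities(qualities)
    patches = np.repeat(np.arange(qualities.size), counts)
    act = np.full(patches.size, activity, dtype=float)
    return SimState(landscape, act, patches)


@pytest.fixture
def state_factory():
    return make_state


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
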