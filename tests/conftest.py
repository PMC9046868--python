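import numpy as np
import pytest

import melsim
from melsim.geometry import GridSpec, default_atlas


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture
def grid8():
    return GridSpec(n_spatial=8, n_structural=8)


@pytest.fixture
def grid16():
    return GridSpec(n_spatial=16, n_structural=16)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_overrides(**treatment):
    """A fast low-resolution scenario for end-to-end solver tests."""
    over = {
        "grid": {"n_spatial": 8, "n_structural": 8},
        "run": {"horizon": 20.0, "snapshot_interval": 5.0},
    }
    if treatment:
        over["treatment"] = treatment
    return over


@pytest.fixture(scope="session")
def reference_runs():
    """Lazily-run cache of full reference-resolution scenario trajectories."""
    cache = {}

    def get(preset_name):
        if preset_name not in cache:
            scn = melsim.preset(preset_name)
            cache[preset_name] = (melsim.simulate(scn), scn)
        return cache[preset_name]

    return get
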