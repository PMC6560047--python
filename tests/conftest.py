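import numpy as np
import pytest

import ringmem as rm


@pytest.fixture(scope="session")
def canonical_rings():
    return rm.build_memory_rings(range(1, 8), (3, 6))


@pytest.fixture(scope="session")
def tax(canonical_rings):
    return rm.link_taxonomy(*canonical_rings)


@pytest.fixture(scope="session")
def small_params():
    # half-length scan block (112 trials): occurrence counts stay divisible
    # by four so rotation balancing remains exact
    return rm.DesignParams(nonrepeat_reps_per_context=2, repeat_reps_per_context=2)


@pytest.fixture(scope="session")
def tiny_truth():
    return rm.GroundTruth(n_voxels=40)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
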