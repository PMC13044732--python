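import numpy as np
import pytest

import bayespose as bp


@pytest.fixture(scope="session")
def phantom24():
    """Small asymmetric phantom shared by estimator tests."""
    return bp.make_phantom_volume("blob-asym", 24, seed=0)


@pytest.fixture(scope="session")
def grid300():
    return bp.build_so3_quadrature(300)


@pytest.fixture(scope="session")
def cache24(phantom24, grid300):
    return bp.TemplateCache(phantom24, grid300, "subtomogram-3d")


@pytest.fixture(scope="session")
def random_rotation_pairs():
    rs = bp.sample_uniform_rotations(200, seed=11)
    return rs[:100], rs[100:]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
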