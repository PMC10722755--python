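import numpy as np
import pytest

from gammashape import ModelSpec, simulate_shape_dgp

COVS = ("x", "x2", "const")


@pytest.fixture(scope="session")
def dataset_n1000():
    """One draw from the shape-parameter DGP at the study's sample size."""
    return simulate_shape_dgp(1000, seed=314159)


@pytest.fixture
def rng():
    return np.random.default_rng(8675309)


@pytest.fixture(params=["shape", "scale", "shape_scale"])
def any_spec(request):
    return ModelSpec(request.param, COVS)
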