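import numpy as np
import pytest

from krigknn import AutocovParams, GridSpec, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def grid5():
    """Coordinates of a small 5x5 grid on the default extent."""
    return make_grid(GridSpec(n_side=5))


@pytest.fixture
def exp_params():
    return AutocovParams(nugget=0.5, psill=2.0, range=0.8, family="exponential")


@pytest.fixture
def sph_params():
    return AutocovParams(nugget=0.25, psill=1.5, range=1.2, family="spherical")


@pytest.fixture
def toy_observed(rng):
    """A small observed data set: coordinates, covariates, response."""
    n, p = 12, 3
    coords = rng.uniform(-1, 1, size=(n, 2))
    X = rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.25])
    z = X @ beta + rng.normal(scale=0.5, size=n)
    return coords, X, z
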