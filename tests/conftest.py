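import math

import numpy as np
import pytest

from hellbayes.families import Normal1D, ParametricFamily


class NormalLocation(ParametricFamily):
    """Normal location family with known sigma (test helper)."""

    def __init__(self, sigma=1.0):
        self.sigma = sigma
        super().__init__(
            name="normal_loc", param_dim=1, data_dim=1,
            param_names=("mu",), param_bounds=((-np.inf, np.inf),),
            support=(-np.inf, np.inf))

    def pdf(self, theta, x):
        mu = np.asarray(theta, dtype=float).reshape(-1)[0]
        x = np.asarray(x, dtype=float)
        z = (x - mu) / self.sigma
        return np.exp(-0.5 * z * z) / (self.sigma * math.sqrt(2 * math.pi))

    def mle(self, sample):
        return np.array([np.mean(sample)])

    def sample(self, theta, n, rng):
        mu = np.asarray(theta, dtype=float).reshape(-1)[0]
        return rng.normal(mu, self.sigma, size=n)


@pytest.fixture
def normal1d():
    return Normal1D()


@pytest.fixture
def normal_loc():
    return NormalLocation()


@pytest.fixture
def wide_grid():
    from hellbayes.disparity import make_grid
    return make_grid((-15.0, 15.0), order=12, n_panels=30)
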