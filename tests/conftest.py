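import numpy as np
import pytest

from graphmr import SummaryPair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pair(
    rng,
    m=10,
    theta=0.2,
    rho=0.0,
    n_invalid=0,
    r_scale=0.5,
    se_scale=0.02,
    bx_scale=0.1,
    n=100_000,
):
    """Random summary pair generated from the bivariate estimate model."""
    b_x = bx_scale * (1.0 + rng.random(m))
    r = np.zeros(m)
    if n_invalid:
        r[:n_invalid] = r_scale * (1.0 + rng.random(n_invalid))
    sx = se_scale * (0.5 + rng.random(m))
    sy = se_scale * (0.5 + rng.random(m))
    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    beta_x = b_x + sx * e1
    beta_y = theta * b_x + r + sy * (rho * e1 + np.sqrt(1 - rho**2) * e2)
    return SummaryPair(
        [f"rs{i}" for i in range(m)], beta_x, sx, beta_y, sy, rho, n, n
    )


def perfect_pair(m=6, theta=0.5, rho=0.0, n=100_000, seed=3):
    """Noise-free pair: beta_y = theta * beta_x exactly."""
    gen = np.random.default_rng(seed)
    beta_x = 0.1 * (1.0 + gen.random(m))
    sx = np.full(m, 0.01)
    sy = np.full(m, 0.02)
    return SummaryPair(
        [f"rs{i}" for i in range(m)], beta_x, sx, theta * beta_x, sy, rho, n, n
    )


@pytest.fixture
def pair_factory(rng):
    def factory(**kwargs):
        return make_pair(rng, **kwargs)

    return factory
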