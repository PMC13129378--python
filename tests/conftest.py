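import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mr4dctreg import Grid, PhantomConfig, make_study

settings.register_profile(
    "ci", deadline=None, max_examples=15, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_study():
    """One deterministic desk-scale phantom study shared across tests."""
    return make_study(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_grid():
    return Grid((16, 16, 16), (1.0, 1.0, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def smooth_svf(grid, seed, max_mag=3.0, sigma=4.0):
    """Seeded smooth random velocity field (shared test-family helper)."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed)
    u = np.stack([gaussian_filter(r.normal(size=grid.shape), sigma)
                  for _ in range(3)])
    peak = np.abs(u).max()
    if peak > 0:
        u = u / peak * max_mag
    return u
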