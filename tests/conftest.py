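import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schemes():
    from photophase.published import schemes

    return schemes()


@pytest.fixture
def grid():
    """The study sampling grid: ZT1-ZT23 every 2 h."""
    return np.arange(1.0, 24.0, 2.0)


@pytest.fixture
def make_series(grid):
    """Build an ExpressionSeries from a mean function, optionally noisy."""
    from photophase.cosinor import ExpressionSeries

    def _make(fn, replicates=1, noise_cv=0.0, seed=0, gene="g", condition="LD"):
        rng = np.random.default_rng(seed)
        t = np.repeat(grid, replicates)
        mean = fn(t)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            level = mean * rng.lognormal(-sigma**2 / 2, sigma, len(t))
        else:
            level = mean
        return ExpressionSeries(gene, condition, t,
                                np.tile(np.arange(replicates), len(grid)), level)

    return _make
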