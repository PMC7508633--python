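import numpy as np
import pytest

from searchsurge import SyntheticConfig, WindowSpec, generate_trend_series


@pytest.fixture(scope="session")
def default_window():
    return WindowSpec()


@pytest.fixture(scope="session")
def null_series():
    """Factory for synthetic no-effect series under the default conditions."""

    def make(seed=0, **overrides):
        cfg = SyntheticConfig(seed=seed, **overrides)
        series, _ = generate_trend_series(cfg)
        return series

    return make


@pytest.fixture(scope="session")
def ar1_sample():
    """Factory for seeded AR(1) samples with burn-in."""

    def make(phi, n, seed=0, sd=1.0, mean=0.0):
        rng = np.random.default_rng(seed)
        e = rng.normal(0.0, sd, n + 100)
        x = np.zeros(n + 100)
        for t in range(1, n + 100):
            x[t] = phi * x[t - 1] + e[t]
        return x[100:] + mean

    return make
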