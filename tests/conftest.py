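import numpy as np
import pytest

from isocod.synthetic import SynthConfig, generate_assemblage
from isocod.trend import TrendConfig


@pytest.fixture(scope="session")
def assemblage():
    """A moderate synthetic assemblage with a linear trend (shared, read-only)."""
    config = SynthConfig(
        n_specimens=150,
        trend=("linear", {"slope": 0.01, "level": 19.4}),
        seed=11,
    )
    records, truth = generate_assemblage(config)
    return config, records, truth


@pytest.fixture
def fast_mcmc():
    """Reduced MCMC settings for quick fits in unit tests."""
    return dict(chains=2, walkers=16, warmup=300, steps=300, n_draws=800,
                ess_threshold=100.0, rhat_threshold=1.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
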