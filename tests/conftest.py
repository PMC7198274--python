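import numpy as np
import pytest

from hybridgp import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small two-panel study shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        n_founders=60,
        m_snps=600,
        n_ril_populations=3,
        rils_per_population=25,
        variance_spec={
            "additive": 1.0,
            "dominance": 0.5,
            "panel": 0.0,
            "structure": 0.3,
            "residual": 0.5,
        },
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
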