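import numpy as np
import pytest

from sociotouch import synth


@pytest.fixture(scope="session")
def small_neural_session():
    """Compact session (8 units, 12 bouts/block), spikes only."""
    cfg = synth.SyntheticConfig(
        n_units={"vS1": 4, "tSTR": 2, "BLA": 2}, n_bouts=12, rng_seed=42
    )
    session, truth = synth.generate_session(cfg, include_behavior=False)
    return session, truth


@pytest.fixture(scope="session")
def behavior_session():
    """Small session including pose-label traces and planted events."""
    cfg = synth.SyntheticConfig(
        n_units={"vS1": 4, "tSTR": 0, "BLA": 0}, n_bouts=15, rng_seed=5
    )
    session, truth = synth.generate_session(cfg)
    return session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
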