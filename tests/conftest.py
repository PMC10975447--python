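import numpy as np
import pytest

from pileflow.simulator import SimConfig, simulate_pile_stack


@pytest.fixture(scope="session")
def pile_run():
    """One deterministic no-avalanche pile-growth render shared by tests."""
    cfg = SimConfig(alpha_true=35.0, duration=12.0, seed=42)
    stack, truth = simulate_pile_stack(cfg)
    return cfg, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
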