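import numpy as np
import pytest

from svakit.synthetic_data import SimulationConfig, simulate_expansion


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulation shared across tests (noise on)."""
    from svakit.synthetic_data import LineagePlan

    plan = [
        LineagePlan("A", None, "hominine", 30, n_diagnostics=2, age=2.0),
        LineagePlan("B", "A", "hs", 25, n_diagnostics=2, age=1.0),
        LineagePlan("C", None, "pt", 30, n_diagnostics=2, deletion=(560, 20), age=1.5),
    ]
    return simulate_expansion(
        SimulationConfig(seed=99, lineages=plan, n_decoy_pairs=2)
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default study-condition simulation (15 lineages, three species)."""
    return simulate_expansion(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_sim():
    return simulate_expansion(
        SimulationConfig(seed=7, mutation_rate=0.0, truncation_prob=0.0, n_decoy_pairs=0, loss_prob=0.0)
    )
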