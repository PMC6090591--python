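import pytest

from phasecycle.simulate import SimulationSpec, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic brood-swap dataset shared across tests."""
    spec = SimulationSpec(n_genes=300, seed=42)
    return simulate_experiment(spec)
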