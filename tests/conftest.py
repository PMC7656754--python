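import numpy as np
import pytest

from protqc.simulator import SCENARIOS, SimulationConfig, generate_study, simulate_study


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_config():
    """Small error-free study: every gene clean, three species."""
    return SimulationConfig(n_genes=8, n_target_species=3, seed=42, scenario_mix={})


@pytest.fixture(scope="session")
def clean_study(clean_config):
    return generate_study(clean_config)


@pytest.fixture(scope="session")
def mixed_bundle(tmp_path_factory):
    """On-disk bundle with every scenario represented."""
    d = tmp_path_factory.mktemp("mixed_bundle")
    cfg = SimulationConfig(
        n_genes=16,
        n_target_species=5,
        seed=7,
        scenario_mix={s: 0.1 for s in SCENARIOS if s != "NONE"},
    )
    simulate_study(cfg, d)
    return d
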