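import numpy as np
import pytest

from cormbind import synthetic as syn


@pytest.fixture(scope="session")
def q_grid():
    return np.linspace(0.0, 50.0, 12)


@pytest.fixture(scope="session")
def default_config():
    return syn.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_ensemble(default_config):
    """Desk-scale ensemble with planted hotspots (shared; treat as read-only)."""
    return syn.gen_trajectory_ensemble(default_config)


@pytest.fixture(scope="session")
def ligand():
    return syn.default_ligand()


@pytest.fixture(scope="session")
def small_protein():
    return syn.gen_protein_model(50, seed=2, trp_positions=(10, 40))
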