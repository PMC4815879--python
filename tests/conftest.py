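import numpy as np
import pytest

from sfxkit import SimulationConfig, UnitCell, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """50-crystal ambiguous dataset with ground truth (session-cached)."""
    config = SimulationConfig(n_crystals=50, seed=11)
    stream, truth = simulate_dataset(config)
    return config, stream, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Unambiguous, full-reflection (p = 1) dataset for scaling tests."""
    config = SimulationConfig(n_crystals=60, seed=12, ambiguity_operator=None,
                              apply_partiality=False, d_min=3.2, i0=1e4)
    stream, truth = simulate_dataset(config)
    return config, stream, truth


@pytest.fixture
def cubic_cell():
    return UnitCell(100.0, 100.0, 100.0, 90.0, 90.0, 90.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
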