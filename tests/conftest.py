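import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tilscore import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized (n=67) cohort, shared read-only across tests."""
    return generate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """n=2,000 cohort for parameter-recovery checks."""
    return generate_cohort(SimulationConfig(seed=7, n_patients=2000))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
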