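import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mobiscope.gps_metrics import HomeLocation


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def home():
    return HomeLocation(50.94, 6.96)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact generated study bundle shared across read-only tests."""
    from mobiscope.synthetic_data import SimulationConfig, generate_study

    root = tmp_path_factory.mktemp("study")
    cfg = SimulationConfig(n_participants=25, days_per_participant=(6, 9),
                           missing_rate=0.03, seed=11)
    generate_study(cfg, root)
    return root
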