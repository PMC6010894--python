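import numpy as np
import pytest

import gcorrect as gc


@pytest.fixture(scope="session")
def panel():
    return gc.DEFAULT_PANEL.copy()


@pytest.fixture(scope="session")
def cohort50k():
    """One mid-sized synthetic cohort under the default study conditions,
    shared by recovery-style tests."""
    cfg = gc.SimulationConfig(n_participants=50_000)
    return gc.simulate_cohort(cfg, seed=20_260_920)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
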