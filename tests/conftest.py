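import numpy as np
import pytest

import gazestate as gs


@pytest.fixture(scope="session")
def geom():
    return gs.default_geometry()


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size study cohort: 12 participants x 2 conditions, 17 min at
    20 Hz, seed 1."""
    return gs.simulate_cohort(gs.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for structural tests: 4 participants x 2 conditions,
    60 s at 20 Hz."""
    return gs.simulate_cohort(gs.SimConfig(n_participants=4, duration_s=60.0, seed=7))


@pytest.fixture(scope="session")
def default_reports(default_cohort):
    """Pipeline reports for every indicator mode on the default cohort."""
    return {
        mode: gs.run_pipeline(default_cohort.sequences, mode)
        for mode in ("PRC", "S", "D", "DS")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
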