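import numpy as np
import pytest

from ramancal import synth
from ramancal.evaluation import run_generic_experiment


@pytest.fixture(scope="session")
def peak_library():
    """Packaged analyte band models and matrix background."""
    return synth.load_peak_library()


@pytest.fixture(scope="session")
def quiet_profile():
    """An instrument with every nuisance term disabled."""
    return synth.InstrumentProfile(
        name="quiet",
        grid_start=100, grid_stop=3425, grid_step=1,
        offset_cm1=0.0, broadening=1.0,
        noise_sd=0.0, baseline_degree=0, baseline_scale=0.0, scatter_sd=0.0,
    )


@pytest.fixture(scope="session")
def desk_experiment():
    """The seeded desk-scale transfer experiment (shared across tests)."""
    return run_generic_experiment(seed=0, scenario="desk")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
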