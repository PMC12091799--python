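import numpy as np
import pytest

from ffrt import (
    FractionalSpec,
    SimulationGrid,
    integrate_classical,
    patient_preset,
)


@pytest.fixture(scope="session")
def patient1():
    return patient_preset(1, "high")


@pytest.fixture(scope="session")
def classical_spec():
    return FractionalSpec(mu=1.0, nu=1.0)


@pytest.fixture(scope="session")
def patient1_classical_traj(patient1):
    """High-accuracy classical trajectory of Patient 1 (high arm) over 400 h."""
    grid = SimulationGrid.for_horizon(400.0, 0.05)
    return integrate_classical(patient1.params, grid, patient1.init)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
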