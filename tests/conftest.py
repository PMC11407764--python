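import numpy as np
import pytest

from synglu import vesicle


@pytest.fixture(scope="session")
def control_run() -> vesicle.SimulationResult:
    """Calibrated control simulation, shared across tests (deterministic)."""
    return vesicle.simulate()


@pytest.fixture(scope="session")
def control_steady_state() -> tuple[vesicle.VesicleState, float]:
    """Polished control steady state (state, molecule count)."""
    return vesicle.find_steady_state()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
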