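import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pumploop import loop as ploop

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated_params() -> ploop.LoopParams:
    return ploop.calibrate_basal()


@pytest.fixture(scope="session")
def fig6_trajectory(calibrated_params) -> ploop.Trajectory:
    """Calibrated loop run with the 100 uM ouabain step at t = 2500."""
    pert = (ploop.Perturbation("ouabain", 2500.0, 100.0),)
    return ploop.simulate(calibrated_params, pert)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
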