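"""Shared fixtures: simulated acquisitions and their schematic fits.

The expensive 19-parameter fits are session-scoped so that recovery,
invariance and acceptance tests share them.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stepwedge as sw

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geom():
    return sw.MachineGeometry()


@pytest.fixture(scope="session")
def wedge():
    return sw.StepWedgeSpec()


@pytest.fixture(scope="session")
def noiseless_scenario():
    return sw.SimulationScenario(noise_rel=0.0, output_ripple=(0.0, 10.0), seed=1)


@pytest.fixture(scope="session")
def noiseless_sim(noiseless_scenario):
    acq, truth = sw.simulate_acquisition(noiseless_scenario)
    return sw.output_correct(acq), truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_sim, geom, wedge):
    acq, _ = noiseless_sim
    profile = sw.extract_time_profile(acq)
    return sw.fit_schematic_profile(profile, geom, wedge, seed=0)


@pytest.fixture(scope="session")
def noisy_scenario():
    return sw.SimulationScenario(noise_rel=0.005, seed=7)


@pytest.fixture(scope="session")
def noisy_sim(noisy_scenario):
    acq, truth = sw.simulate_acquisition(noisy_scenario)
    return sw.output_correct(acq), truth


@pytest.fixture(scope="session")
def noisy_fit(noisy_sim, geom, wedge):
    acq, _ = noisy_sim
    profile = sw.extract_time_profile(acq)
    return sw.fit_schematic_profile(profile, geom, wedge, seed=0)


@pytest.fixture(scope="session")
def noisy_transverse_profiles(noisy_sim, noisy_fit):
    acq, _ = noisy_sim
    return sw.extract_transverse_profiles(acq, noisy_fit)


@pytest.fixture()
def small_acquisition():
    """A small random acquisition for I/O round-trip tests."""
    rng = np.random.default_rng(42)
    n, c = 120, 640
    return sw.DetectorAcquisition(
        signal=rng.uniform(0.0, 2.0, size=(n, c)),
        monitor=rng.uniform(0.9, 1.1, size=n),
        dt_s=1.0 / 30.0,
        meta={"machine_id": "T1", "note": "fixture"},
    )
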