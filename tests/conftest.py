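import numpy as np
import pytest

from chancoupler import synthgen as sg


@pytest.fixture(scope="session")
def short_protocol():
    return sg.StepProtocol(n_sweeps=50, step_ms=10.0)


@pytest.fixture(scope="session")
def independent_sweeps(short_protocol):
    """Small independent-pair (phi=0) sweep set with default kinetics."""
    model = sg.GatingModel(coupling_fraction=0.0)
    return sg.simulate_sweeps(model, short_protocol, seed=123)


@pytest.fixture(scope="session")
def noiseless_coupled_sweeps():
    """Noiseless concerted-dimer (phi=1) sweeps: only levels 0 and 2 occur."""
    model = sg.GatingModel(coupling_fraction=1.0, noise_sd=0.0)
    protocol = sg.StepProtocol(n_sweeps=80, step_ms=10.0)
    return sg.simulate_sweeps(model, protocol, seed=11)


@pytest.fixture(scope="session")
def dimer_bleach_population():
    """2,000 dimer photobleaching traces at the standard study conditions."""
    params = sg.BleachPopulationParams(
        n_subunits=2, p_active=0.7, bleach_rate=0.2, frame_interval_s=0.1,
        noise_sd=0.1, n_molecules=2000, n_frames=300,
    )
    return sg.simulate_bleach_population(params, seed=7)
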