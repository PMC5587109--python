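import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from p300composer import decoder as dec
from p300composer import session_runner as sr
from p300composer.matrix_engine import load_bundled_matrices
from p300composer.signal_sim import RecordingParams


@pytest.fixture(scope="session")
def matrices():
    return load_bundled_matrices()


def make_trained_system(noise_sd: float, amplitude: float = 5.0, seed: int = 123):
    """Calibrate a fresh pipeline at the given SNR and return (user, system)."""
    user = sr.SimulatedUser(RecordingParams(noise_sd=noise_sd, p300_amplitude=amplitude))
    system = sr.BciSystem()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        blocks, _ = sr.simulate_calibration(user, system, seed=seed)
        sr.train_from_calibration(system, blocks)
    return user, system


@pytest.fixture(scope="session")
def noiseless_system():
    """User + system calibrated in the noiseless regime."""
    return make_trained_system(noise_sd=0.0)


@pytest.fixture(scope="session")
def default_system():
    """User + system calibrated at the default simulated SNR."""
    return make_trained_system(noise_sd=4.0)
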