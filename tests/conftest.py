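import numpy as np
import pytest

from tvorsim.chair_kinematics import StimulusProtocol, make_trapezoid_profile
from tvorsim.dynamic_model import ModelParameters
from tvorsim.synthetic_data import NoiseSpec, generate_trial


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def standard_step(protocol):
    """Standard 20 cm trapezoid step with padding before and after motion."""
    return make_trapezoid_profile(protocol, dt=0.002, pad_before=0.1, pad_after=1.3)


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseSpec(velocity_noise_sd=0.0, quick_phase_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_trial(default_params, protocol, quiet_noise):
    return generate_trial(
        default_params, protocol, quiet_noise, seed=0, meta={"distance": 70.0}
    )


def make_noiseless_trials(params, n=2, seed0=0, **kwargs):
    """Alternating-direction noiseless trials generated from the forward model."""
    quiet = NoiseSpec(velocity_noise_sd=0.0, quick_phase_rate=0.0)
    trials = []
    for i in range(n):
        proto = StimulusProtocol(direction="left" if i % 2 == 0 else "right")
        trials.append(
            generate_trial(
                params, proto, quiet, seed=seed0 + i, meta={"distance": params.distance}, **kwargs
            )
        )
    return trials


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
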