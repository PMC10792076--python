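import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gaitval.synthetic import (NoiseModel, RaterModel, forward_kinematics,
                               generate_subject)


@pytest.fixture(scope="session")
def subject():
    return generate_subject(rng_seed=3)


@pytest.fixture(scope="session")
def clean_trial(subject):
    """One zero-noise, identity-rater trial with ground truth."""
    return forward_kinematics(subject, 3, RaterModel.identity(),
                              NoiseModel.zero(), rng_seed=11)


@pytest.fixture(scope="session")
def noisy_trial(subject):
    """One trial with all default noise channels active."""
    return forward_kinematics(subject, 3, RaterModel(rater_id=1),
                              NoiseModel(), rng_seed=12)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240116)
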