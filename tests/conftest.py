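import numpy as np
import pytest

from squatmech.model import LoadCondition, Participant
from squatmech.synthetic import (CohortSpec, NoiseLevels, generate_participant,
                                 generate_squat_trial, generate_static_trial,
                                 truth_model)


@pytest.fixture(scope="session")
def participant():
    return Participant("P01", 65.67, 1.72, 2.0, 80.0, "normal")


@pytest.fixture(scope="session")
def model(participant):
    return truth_model(participant)


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free study conditions (deterministic limits)."""
    return CohortSpec(noise=NoiseLevels(0.0, 0.0, 0.0, 0.05))


@pytest.fixture(scope="session")
def noisy_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def quiet_trial(participant, model, quiet_spec):
    """One noise-free bodyweight squat trial with ground truth attached."""
    load = LoadCondition(0.0, participant.one_rm)
    return generate_squat_trial(participant, load, model, quiet_spec, seed=7)


@pytest.fixture(scope="session")
def noisy_trial(participant, model, noisy_spec):
    load = LoadCondition(0.0, participant.one_rm)
    return generate_squat_trial(participant, load, model, noisy_spec, seed=7)


@pytest.fixture(scope="session")
def static_trial(participant, model, noisy_spec):
    return generate_static_trial(participant, model, noisy_spec, seed=3)


@pytest.fixture(scope="session")
def valgus_participant():
    return generate_participant("valgus", 11, CohortSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
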