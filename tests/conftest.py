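import pytest

from imikin.datatypes import Condition
from imikin.simulate import GeneratorSpec, generate_trial


@pytest.fixture(scope="session")
def quiet_spec() -> GeneratorSpec:
    """Generator with no injected artifacts (clean-world baseline)."""
    return GeneratorSpec(seed=11, spike_rate=0.0, tms_artifact_amplitude_cm=0.0)


@pytest.fixture(scope="session")
def condition() -> Condition:
    return Condition("PMv", "imitation", "meaningful", "hand")


@pytest.fixture(scope="session")
def clean_trial_pair(quiet_spec, condition):
    """One artifact-free generated trial plus its ground truth."""
    return generate_trial(quiet_spec, condition, participant_id=1)


@pytest.fixture(scope="session")
def noiseless_trial_pair(condition):
    """A trial with zero position noise (speeds are exactly the bells)."""
    spec = GeneratorSpec(
        seed=13, noise_sd_cm=0.0, spike_rate=0.0, tms_artifact_amplitude_cm=0.0
    )
    return generate_trial(spec, condition, participant_id=1)


@pytest.fixture(scope="session")
def noisy_trial_pair(condition):
    """One trial with spikes and stimulation artifacts injected."""
    spec = GeneratorSpec(seed=7, spike_rate=2.0)
    return generate_trial(spec, condition, participant_id=2)


@pytest.fixture(scope="session")
def spiked_trial_pair(condition):
    """Spikes only (no stimulation artifacts): the spike-detection world."""
    spec = GeneratorSpec(seed=17, spike_rate=2.0, tms_artifact_amplitude_cm=0.0)
    return generate_trial(spec, condition, participant_id=2)
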