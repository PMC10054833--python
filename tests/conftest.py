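import numpy as np
import pytest

from pdglove.synth import ParticipantProfile


@pytest.fixture
def zero_profile() -> ParticipantProfile:
    """A participant with no symptoms: all severities zero."""
    return ParticipantProfile("Z00")


@pytest.fixture
def tremor_profile() -> ParticipantProfile:
    """Full tremor at 7 Hz, completely suppressed by medication."""
    return ParticipantProfile("T01", tremor_severity=1.0, tremor_freq_hz=7.0,
                              med_tremor_suppression=1.0)


@pytest.fixture
def brady_profile() -> ParticipantProfile:
    """Full bradykinesia, strongly medication-responsive."""
    return ParticipantProfile("B01", brady_severity=1.0, med_brady_suppression=0.9)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
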