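import numpy as np
import pytest

from dynquant import AcquisitionParams, BindingEvent, MicrotubuleObservation


@pytest.fixture
def acq():
    return AcquisitionParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_observation(mt_id, durations_s, length_um=10.0, duration_s=120.0,
                     conc_nM=1.0, censored_flags=None):
    """Build an observation with events of the given (frame-multiple) durations."""
    censored_flags = censored_flags or [False] * len(durations_s)
    events = [
        BindingEvent(mt_id=mt_id, t_start_s=i * 10.0, t_end_s=i * 10.0 + d,
                     censored=c)
        for i, (d, c) in enumerate(zip(durations_s, censored_flags))
    ]
    return MicrotubuleObservation(
        mt_id=mt_id, length_um=length_um, observation_duration_s=duration_s,
        conc_nM=conc_nM, events=events,
    )
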