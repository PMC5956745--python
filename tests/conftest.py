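import numpy as np
import pytest

import epsckit as ek


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quantal_model():
    """Wild-type-like quantal model: 20 channels of -0.69 pA at -60 mV."""
    return ek.QuantalModel(n_channels=20, unitary_current=-0.69,
                           tau_rise=0.15, tau_decay=1.3)


@pytest.fixture
def sharp_rise_model():
    """Same model with a near-instant rise, so essentially all channels
    are still open at the observable peak."""
    return ek.QuantalModel(n_channels=20, unitary_current=-0.69,
                           tau_rise=0.01, tau_decay=1.3)


@pytest.fixture
def mepsc_recording(quantal_model):
    """A 60 s equivalent mEPSC recording at 3 Hz with 1 pA noise."""
    session = ek.SessionModel(event_rate=3.0, noise_sd=1.0,
                              sweep_duration=1000.0, n_sweeps=60, seed=7)
    rec, truth = ek.simulate_mepsc_recording(quantal_model, session)
    return rec, truth


def detect_screen_align(rec, k=3.0):
    """Standard detection chain used by several test modules."""
    _, sd = ek.estimate_baseline_noise(rec)
    events = ek.detect_events(rec, k=k, noise_sd=sd)
    ek.screen_events(events, rec, noise_sd=sd)
    return ek.align_and_average(events, rec), events, sd
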