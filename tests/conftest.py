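import numpy as np
import pytest

from respvar import breaths as br
from respvar import signal as sg
from respvar import simulate as simu


@pytest.fixture(scope="session")
def eupnea_spec():
    return simu.BreathProcessSpec(
        mean_ti=1.7, mean_te=2.3, sd_ti=0.15, sd_te=0.2, ar1_rho=0.3, duration=330
    )


@pytest.fixture(scope="session")
def uniform_truth():
    """Zero-variance breathing: 60 contiguous 5-s breaths over 300 s."""
    spec = simu.BreathProcessSpec(
        mean_ti=2.0, mean_te=3.0, sd_ti=0.0, sd_te=0.0, sd_amp=0.0, duration=300
    )
    return simu.simulate_breath_sequence(spec, seed=1)


@pytest.fixture(scope="session")
def clean_recording(eupnea_spec):
    """Noiseless rendered eupnoea (dominant z axis, no drift)."""
    bt = simu.simulate_breath_sequence(eupnea_spec, seed=11)
    rec = simu.render_acceleration(bt, fs=10.0, noise_sd=0.0, drift_rate=0.0, seed=11)
    return rec, bt


@pytest.fixture(scope="session")
def conditioned(clean_recording):
    rec, bt = clean_recording
    return sg.preprocess(rec), bt


@pytest.fixture(scope="session")
def small_cohort():
    """22 + 22 subjects, truth only (no rendering), default links."""
    spec = simu.CohortSpec(n_patients=22, n_controls=22, seed=5, render=False)
    return simu.simulate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_tables(small_cohort):
    feats = simu.cohort_feature_table(small_cohort)
    from respvar.compare import subjects_to_frame

    subjects = subjects_to_frame(simu.cohort_subject_records(small_cohort))
    return feats, subjects


def sine_signal(freq=0.25, fs=10.0, duration=300.0, amp=1.0, phase=0.0):
    t = np.arange(0, duration, 1 / fs)
    return sg.RespSignal(t=t, x=amp * np.sin(2 * np.pi * freq * t + phase), fs=fs)


@pytest.fixture
def make_sine():
    return sine_signal
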