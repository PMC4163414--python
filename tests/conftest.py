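import numpy as np
import pytest

from hhtseizure import RunConfig, SeizurePredictor, SynthParams, generate_patient

FS = 256.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory: pure sinusoid at a given frequency/amplitude/duration."""

    def make(freq_hz, amp=1.0, duration_s=30.0, fs=FS, phase=0.0):
        t = np.arange(int(duration_s * fs)) / fs
        return amp * np.sin(2 * np.pi * freq_hz * t + phase)

    return make


@pytest.fixture(scope="session")
def small_patient():
    """A compact gamma-boost patient shared by the pipeline-level tests."""
    params = SynthParams(preictal_min=10.0, interictal_mean_min=15.0,
                         interictal_sd_min=1.0)
    return generate_patient(2, 2, params, seed=7)


@pytest.fixture(scope="session")
def small_results(small_patient):
    """Fitted leave-one-seizure-out results on the small patient."""
    return SeizurePredictor.from_synthetic(small_patient, RunConfig()).fit()
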