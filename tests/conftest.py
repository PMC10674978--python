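import numpy as np
import pytest

from cecgstress.synthetic import SynthConfig, gen_rr_series, render_ecg


@pytest.fixture
def clean_signal():
    """~96 s of synthetic ECG at 200 Hz, 1 mV R peaks, light noise."""
    rr = gen_rr_series(120, 800, 40, seed=1)
    sig, gt = render_ecg(rr, fs=200.0, r_amp_mv=1.0, noise_sd_mv=0.02, seed=2)
    return sig, gt


@pytest.fixture
def long_clean_signal():
    """~3 min of signal, room for a sparse artifact to keep the coarse check on."""
    rr = gen_rr_series(230, 800, 40, seed=11)
    sig, gt = render_ecg(rr, fs=200.0, r_amp_mv=1.0, noise_sd_mv=0.02, seed=12)
    return sig, gt


def one_artifact_config(duration_s: float, amp_mv: float, dur_s: float) -> SynthConfig:
    """Exactly one artifact in a signal of the given duration."""
    return SynthConfig(
        fs=200.0,
        duration_s=duration_s,
        artifact_rate_per_min=60.0 / duration_s,
        artifact_amp_mv=amp_mv,
        artifact_dur_s=dur_s,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
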