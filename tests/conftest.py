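import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vfegm as v

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def sinusoid_pair() -> v.EGMPair:
    """Noiseless, jitter-free 5 Hz sinusoid on both channels (3 s at 200 Hz)."""
    cfg = v.VFSignalConfig(
        f0=5.0,
        duration=3.0,
        fs=200.0,
        envelope_lv=(1.0,),
        envelope_rv=(1.0,),
        jitter_sd=0.0,
        noise_sd_lv=0.0,
        noise_sd_rv=0.0,
        coupling=1.0,
        seed=1,
    )
    return v.generate_vf_pair(cfg)


@pytest.fixture
def harmonic_pair() -> v.EGMPair:
    """Noiseless five-harmonic ladder at f0 = 4.74 Hz, 6 s at 200 Hz."""
    cfg = v.VFSignalConfig(
        f0=4.74,
        envelope_lv=(1.0,) * 5,
        envelope_rv=(1.0,) * 5,
        jitter_sd=0.0,
        noise_sd_lv=0.0,
        noise_sd_rv=0.0,
        seed=2,
    )
    return v.generate_vf_pair(cfg)


@pytest.fixture
def default_pair() -> v.EGMPair:
    """One patient-like pair with the default LV/RV presets."""
    return v.generate_vf_pair(v.VFSignalConfig(seed=11))


def uniform_spectrum(fs: float = 200.0, nfft: int = 4096) -> v.SpectrumEstimate:
    """Flat unit-area spectrum on the Welch grid (white in-band density)."""
    freqs = np.arange(nfft // 2 + 1) * fs / nfft
    df = fs / nfft
    pn = np.full(freqs.size, 1.0 / (freqs.size * df))
    return v.SpectrumEstimate(freqs=freqs, pn=pn, resolution=df, mainlobe=fs / 256)
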