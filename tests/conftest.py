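import numpy as np
import pytest

import hdtcardio as hc


@pytest.fixture()
def rng():
    return np.random.default_rng(20151123)


@pytest.fixture(scope="session")
def ipfm_recording():
    """One 600-s IPFM recording with LF/HF modulation plus its synthetic ECG
    (respiratory QRS modulation at 0.27 Hz, 20 dB SNR); shared by the
    detection and end-to-end spectral tests."""
    cfg = hc.RrGeneratorConfig(
        duration_s=600.0,
        mean_rr_ms=1000.0,
        components=[
            hc.Modulation(0.10, 300.0, bandwidth_hz=0.06),
            hc.Modulation(0.25, 700.0, bandwidth_hz=0.08),
        ],
        seed=1234,
    )
    beat_times, nn_ms = hc.generate_rr(cfg)
    ecg = hc.generate_ecg(
        beat_times,
        resp_rate_hz=0.27,
        modulation_depth=0.10,
        noise_snr_db=20.0,
        rng=np.random.default_rng(99),
    )
    return {"config": cfg, "beat_times": beat_times, "nn_ms": nn_ms, "ecg": ecg}


@pytest.fixture()
def constant_beats():
    """600 beats at exactly 1000 ms."""
    return hc.BeatSeries(times=np.arange(600, dtype=float))
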