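"""Frequency-domain chain on a known tachogram.

Resamples a beat series at 5 Hz, estimates the Welch periodogram (240-s Hann
windows, 90 % overlap), applies the broadband order-3..11 smoothing and
integrates the VLF / LF / HF bands — the configured modulation variances are
the ground truth the chain should return.
"""

import hdtcardio as hc

cfg = hc.RrGeneratorConfig(
    duration_s=600,
    components=[
        hc.Modulation(0.10, 600.0, bandwidth_hz=0.06),
        hc.Modulation(0.25, 300.0, bandwidth_hz=0.08),
    ],
    seed=903,
)
t, _ = hc.generate_rr(cfg)
series = hc.resample_series(hc.BeatSeries(times=t), "nn")
raw = hc.welch_psd(series)
smoothed = hc.smooth_psd(raw)
bp = hc.band_powers(smoothed)

print(f"series: {series.values.size} samples at {series.fs:.0f} Hz "
      f"({series.duration:.0f} s), {raw.n_windows} Welch windows")
print(f"grid spacing {raw.freqs[1]-raw.freqs[0]:.5f} Hz (= 1/240)")
print(f"VLF {bp.vlf:7.1f} ms^2   (no VLF modulation configured)")
print(f"LF  {bp.lf:7.1f} ms^2   (configured 600)")
print(f"HF  {bp.hf:7.1f} ms^2   (configured 300)")
print(f"LF/HF {bp.lf_hf:5.2f}        (configured 2.0)")
print(f"log HF {bp.log_hf:5.2f} log-ms^2")
print()
print("Single-seed band powers scatter by ~10-20 % (few effective spectral")
print("degrees of freedom in 600 s); across seeds they are unbiased.")
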