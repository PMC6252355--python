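"""Frequency-domain autonomic indices.

The beat-indexed series (N-N intervals, DBP, QRS amplitude) is linearly
interpolated at 10 Hz and resampled at 5 Hz; a Welch periodogram is estimated
with 240-s Hann windows overlapping by 90 %, then smoothed with a broadband
moving average whose order rises with frequency from 3 to 11; band powers are
integrated over VLF (0.005-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz).
The breathing rate is the spectral centroid of the ECG-derived respiration
(EDR) spectrum between 0.10 and 0.50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

from .beats import BeatSeries
from .errors import (
    CoverageError,
    DomainError,
    InsufficientDataError,
    SpectralStateError,
    UndefinedRateError,
)

VLF_BAND = (0.005, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
EDR_BAND = (0.10, 0.50)

WINDOW_S = 240.0
OVERLAP = 0.9
TARGET_FS = 5.0
INTERP_FS = 10.0


@dataclass
class UniformSeries:
    """Uniformly resampled beat-value series ready for spectral analysis."""

    fs: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise DomainError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("uniform series must be finite")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass
class PowerSpectrum:
    """One-sided power spectral density with raw/smoothed state."""

    freqs: np.ndarray
    density: np.ndarray
    state: str
    window_s: float
    overlap: float
    n_windows: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.state not in ("raw", "smoothed"):
            raise SpectralStateError(f"unknown spectrum state {self.state!r}")
        if np.any(self.density < 0):
            raise DomainError("spectral density must be non-negative")

    def total_power(self) -> float:
        return float(np.trapezoid(self.density, self.freqs))

    def band_power(self, f_lo: float, f_hi: float) -> float:
        """Trapezoidal integral over [f_lo, f_hi] with interpolated edges."""
        if self.freqs[0] > f_lo + 1e-12 or self.freqs[-1] < f_hi - 1e-12:
            raise CoverageError(
                f"grid [{self.freqs[0]:.4f}, {self.freqs[-1]:.4f}] Hz does not "
                f"cover band [{f_lo}, {f_hi}] Hz"
            )
        inside = (self.freqs > f_lo) & (self.freqs < f_hi)
        f = np.concatenate([[f_lo], self.freqs[inside], [f_hi]])
        d = np.concatenate(
            [
                [np.interp(f_lo, self.freqs, self.density)],
                self.density[inside],
                [np.interp(f_hi, self.freqs, self.density)],
            ]
        )
        return float(np.trapezoid(d, f))


@dataclass
class BandPowers:
    """Integrated band powers with the LF/HF ratio and log10 transforms."""

    vlf: float
    lf: float
    hf: float

    @property
    def lf_hf(self) -> float:
        return self.lf / self.hf

    @property
    def log_vlf(self) -> float:
        return float(np.log10(self.vlf))

    @property
    def log_lf(self) -> float:
        return float(np.log10(self.lf))

    @property
    def log_hf(self) -> float:
        return float(np.log10(self.hf))

    @property
    def log_lf_hf(self) -> float:
        return float(np.log10(self.lf_hf))


def resample_series(
    beats: BeatSeries, field: str = "nn", mode: str = "drop"
) -> UniformSeries:
    """Linear interpolation of a beat-indexed series at 10 Hz, decimated to
    5 Hz by taking every second sample.

    ``field`` selects the beat value: ``nn`` (interval in ms, attributed to
    the later beat), ``dbp``/``sbp`` (mmHg) or ``qrs`` (mV).  In ``drop`` mode
    invalid beats simply leave a gap that the linear interpolation bridges; in
    ``interpolate`` mode the invalid beats' values are first re-estimated at
    their original times from the neighbouring valid values — for linear
    interpolation the resulting uniform series is identical, so the mode only
    matters for beat-domain consumers.
    """
    if field == "nn":
        t, v = beats.nn_intervals()
    else:
        t, v = beats.beat_values(field)
    if mode == "interpolate":
        t_all = beats.times if field != "nn" else beats.times[1:]
        v = np.interp(t_all, t, v)
        t = t_all
    if t.size < 2:
        raise InsufficientDataError("need at least 2 valid beats to resample")
    grid10 = np.arange(t[0], t[-1] + 1e-12, 1.0 / INTERP_FS)
    interp = np.interp(grid10, t, v)
    return UniformSeries(fs=TARGET_FS, values=interp[::2], start_time=t[0])


def welch_psd(
    series: UniformSeries,
    window_s: float = WINDOW_S,
    overlap: float = OVERLAP,
    detrend: str = "linear",
) -> PowerSpectrum:
    """Welch periodogram: Hann windows of ``window_s`` seconds overlapping by
    ``overlap``, per-window linear detrend (switchable to mean removal), FFT
    spectra averaged over windows.  One-sided density normalised so its
    integral matches the variance of the detrended series.
    """
    if series.duration < window_s:
        raise InsufficientDataError(
            f"series duration {series.duration:.0f} s < the {window_s:.0f}-s "
            "window required for spectral analysis"
        )
    nperseg = int(round(window_s * series.fs))
    hop = int(round(nperseg * (1 - overlap)))
    noverlap = nperseg - hop
    freqs, psd = _sig.welch(
        series.values,
        fs=series.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
    )
    n_windows = (series.values.size - nperseg) // hop + 1
    return PowerSpectrum(
        freqs=freqs,
        density=psd,
        state="raw",
        window_s=window_s,
        overlap=overlap,
        n_windows=n_windows,
    )


def _smoothing_orders(freqs: np.ndarray, f_lo: float, f_hi: float,
                      k_lo: int, k_hi: int) -> np.ndarray:
    frac = np.clip((freqs - f_lo) / (f_hi - f_lo), 0.0, 1.0)
    k = k_lo + (k_hi - k_lo) * frac
    return (2 * np.round((k - 1) / 2) + 1).astype(int)


def smooth_psd(
    spectrum: PowerSpectrum,
    f_range: tuple[float, float] = (VLF_BAND[0], HF_BAND[1]),
    order_range: tuple[int, int] = (3, 11),
) -> PowerSpectrum:
    """Broadband smoothing: centred moving average whose odd order rises
    linearly with frequency from 3 at the lowest analysed frequency to 11 at
    the highest; windows shrink symmetrically at the grid edges.  Flat spectra
    are left unchanged and total power is preserved to within ~2 %.
    """
    if spectrum.state != "raw":
        raise SpectralStateError("spectrum is already smoothed")
    orders = _smoothing_orders(spectrum.freqs, *f_range, *order_range)
    d = spectrum.density
    n = d.size
    out = np.empty(n)
    for i in range(n):
        h = min(orders[i] // 2, i, n - 1 - i)
        out[i] = d[i - h : i + h + 1].mean()
    return replace(spectrum, density=out, state="smoothed")


def band_powers(spectrum: PowerSpectrum) -> BandPowers:
    """Integrate the smoothed spectrum over the VLF, LF and HF bands."""
    if spectrum.state != "smoothed":
        raise SpectralStateError("band powers are defined on the smoothed spectrum")
    return BandPowers(
        vlf=spectrum.band_power(*VLF_BAND),
        lf=spectrum.band_power(*LF_BAND),
        hf=spectrum.band_power(*HF_BAND),
    )


def edr_central_frequency(
    qrs_series: UniformSeries,
    band: tuple[float, float] = EDR_BAND,
    method: str = "centroid",
) -> float:
    """Mean breathing rate (Hz) from the EDR (QRS-amplitude) spectrum.

    The central frequency is the power-weighted mean frequency (spectral
    centroid) of the smoothed EDR spectrum within ``band``; ``method="argmax"``
    returns the in-band peak frequency instead.
    """
    spec = smooth_psd(welch_psd(qrs_series))
    m = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    p = spec.density[m]
    f = spec.freqs[m]
    total = np.trapezoid(p, f)
    if total <= 0:
        raise UndefinedRateError("no spectral power in the respiratory band")
    if method == "argmax":
        return float(f[np.argmax(p)])
    return float(np.trapezoid(f * p, f) / total)
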