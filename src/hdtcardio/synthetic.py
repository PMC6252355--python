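"""Synthetic recordings and cohorts with known ground truth.

Every stage of the pipeline is testable against this module:

* :func:`generate_rr` — an integral pulse frequency modulation (IPFM) beat
  generator: an instantaneous R-R signal (mean interval plus band-limited
  modulations) is converted to a rate, integrated, and a beat emitted per
  unit area.  IPFM produces beat *times*, which the waveform synthesisers
  and the interpolation step need; an AR interval model would not.
* :func:`generate_ecg` / :func:`generate_bp` — 200-Hz waveforms with PQRST
  templates (respiratory QRS-amplitude modulation) and per-beat pressure
  pulses matching prescribed SBP/DBP targets.
* :func:`generate_cohort` — multi-subject session tables (2 groups x 5
  timepoints x 2 postures, supine only during bed rest) with subject random
  intercepts and configurable group x time fixed effects, returned together
  with the ground-truth effect table.

The configured variance of an R-R modulation component is the *realized*
N-N band variance as the spectral chain measures it.  Both deterministic
attenuations of that chain — interval averaging over one beat in the IPFM
loop (amplitude sinc(f*T)) and the linear-interpolation resampler
(amplitude sinc^2(f*T)) — are therefore pre-compensated at the component's
centre frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .beats import WaveformRecord
from .errors import DomainError, InfeasibleConfigError
from .normalize import LOG_INDICES, TIMEPOINTS
from . import reference_cohort

DEFAULT_SEED = 20151123

#: sessions actually recorded: supine at every timepoint, sitting only at the
#: pre/post postural tests
SESSION_GRID = [
    (tp, pos)
    for tp in TIMEPOINTS
    for pos in (("supine", "sitting") if tp in ("BDC-7", "R+10") else ("supine",))
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Scaling noise (for DFA oracles and 1/f backgrounds)
# ---------------------------------------------------------------------------

def generate_scaling_noise(beta: float, n: int, rng=None) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^beta (spectral
    synthesis).  beta = 0 is white, beta = 1 pink, beta = 2 Brownian-like;
    DFA yields alpha = (beta + 1) / 2."""
    rng = _rng(rng)
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spec, n)
    return (x - x.mean()) / x.std()


# ---------------------------------------------------------------------------
# IPFM R-R generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Modulation:
    """One band-limited autonomic modulation of the instantaneous R-R signal.

    ``variance_ms2`` is the realized N-N band variance; ``pure_tone`` swaps
    the default filtered-Gaussian realisation for a sinusoid at the centre
    frequency (useful for analytic tests).
    """

    center_hz: float
    variance_ms2: float
    bandwidth_hz: float = 0.08
    pure_tone: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.center_hz < 0.5:
            raise DomainError("modulation frequency must lie in (0, 0.5) Hz")
        if self.variance_ms2 < 0:
            raise DomainError("modulation variance must be >= 0")


@dataclass
class RrGeneratorConfig:
    duration_s: float = 600.0
    mean_rr_ms: float = 1000.0
    components: list[Modulation] = field(default_factory=list)
    onef_exponent: float = 1.0
    onef_variance_ms2: float = 0.0
    seed: int | None = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 300 <= self.mean_rr_ms <= 2000:
            raise DomainError("mean R-R must lie in [300, 2000] ms")
        if self.onef_variance_ms2 < 0:
            raise DomainError("1/f variance must be >= 0")


def _chain_gain(f_hz, mean_rr_ms: float):
    """Amplitude attenuation of the measurement chain at frequency f:
    sinc(f T) from interval averaging in the IPFM loop times sinc^2(f T)
    from the linear-interpolation resampler at the mean beat period T."""
    return np.sinc(np.asarray(f_hz) * mean_rr_ms / 1000.0) ** 3


def _analysis_band(center_hz: float) -> tuple[float, float]:
    """The spectral-analysis band (VLF/LF/HF) a component's centre falls in;
    the component's realized variance is calibrated within this band."""
    from .spectral import HF_BAND, LF_BAND, VLF_BAND

    for band in (VLF_BAND, LF_BAND):
        if center_hz < band[1]:
            return band
    return HF_BAND


def _band_component(
    comp: Modulation, duration_s: float, mean_rr_ms: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited Gaussian modulation synthesised in the frequency domain.

    The post-chain target spectrum follows a 4th-order band-pass magnitude
    shape; each line is pre-amplified by the inverse chain gain, and the
    realisation is scaled so its variance inside the component's analysis
    band equals the configured value once the chain attenuation has acted.
    Returns (time grid at 5 Hz, values in ms).
    """
    fs_lo = 5.0
    n = int(duration_s * fs_lo) + 1
    f = np.fft.rfftfreq(n, d=1.0 / fs_lo)
    lo = max(comp.center_hz - comp.bandwidth_hz / 2, 1e-4)
    hi = comp.center_hz + comp.bandwidth_hz / 2
    sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=fs_lo, output="sos")
    _, h = _sig.sosfreqz(sos, worN=f, fs=fs_lo)
    shape = np.abs(h) ** 2  # zero-phase (two-pass) band shape
    z = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    x_post = shape * z
    x_post[0] = 0.0
    band = _analysis_band(comp.center_hz)
    mask = (f >= band[0]) & (f <= band[1])
    v_band = np.fft.irfft(np.where(mask, x_post, 0.0), n).var()
    if v_band <= 0:
        raise InfeasibleConfigError("degenerate band component")
    scale = np.sqrt(comp.variance_ms2 / v_band)
    gain = np.clip(_chain_gain(f, mean_rr_ms), 0.2, None)
    x_pre = np.fft.irfft(scale * x_post / gain, n)
    return np.arange(n) / fs_lo, x_pre


def generate_rr(
    config: RrGeneratorConfig, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate beat times (s) and N-N intervals (ms) by IPFM.

    The instantaneous interval signal rr(t) = mean + sum of modulations is
    inverted to a rate and integrated on a 200-Hz grid; a beat is emitted
    each time unit area accumulates.  Raises
    :class:`InfeasibleConfigError` when the modulation power drives the
    instantaneous rate to zero or below.
    """
    rng = _rng(rng if rng is not None else config.seed)
    fs = 200.0
    t = np.arange(0.0, config.duration_s, 1.0 / fs)
    x = np.zeros(t.size)
    for comp in config.components:
        if comp.variance_ms2 == 0:
            continue
        if comp.pure_tone:
            sd = np.sqrt(comp.variance_ms2) / float(
                _chain_gain(comp.center_hz, config.mean_rr_ms)
            )
            phase = rng.uniform(0, 2 * np.pi)
            x += np.sqrt(2.0) * sd * np.sin(2 * np.pi * comp.center_hz * t + phase)
        else:
            t_lo, vals = _band_component(comp, config.duration_s, config.mean_rr_ms, rng)
            x += np.interp(t, t_lo, vals)
    if config.onef_variance_ms2 > 0:
        fs_lo = 5.0
        n_lo = int(config.duration_s * fs_lo) + 1
        bg = generate_scaling_noise(config.onef_exponent, n_lo, rng)
        x += np.interp(t, np.arange(n_lo) / fs_lo, bg) * np.sqrt(config.onef_variance_ms2)
    rr_inst = config.mean_rr_ms + x
    if np.any(rr_inst <= 50.0):
        raise InfeasibleConfigError(
            "modulation power drives the instantaneous rate to or below zero"
        )
    rate = 1000.0 / rr_inst  # beats per second
    area = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2) / fs])
    n_beats = int(np.floor(area[-1]))
    beat_times = np.interp(np.arange(n_beats + 1, dtype=float), area, t)
    nn_ms = np.diff(beat_times) * 1000.0
    return beat_times, nn_ms


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

_PQRST = (
    # (amplitude fraction of R, offset s, width s)
    (0.12, -0.18, 0.025),   # P
    (-0.08, -0.035, 0.010),  # Q
    (1.00, 0.0, 0.012),      # R
    (-0.18, 0.035, 0.010),   # S
    (0.30, 0.22, 0.050),     # T
)


def generate_ecg(
    beat_times: np.ndarray,
    fs: float = 200.0,
    resp_rate_hz: float = 0.27,
    modulation_depth: float = 0.0,
    noise_snr_db: float | None = None,
    r_amplitude_mv: float = 1.4,
    baseline_drift: tuple[float, float] | None = None,
    rng=None,
) -> WaveformRecord:
    """Synthetic single-lead ECG: PQRST templates at the given beat times,
    with the R amplitude multiplied by (1 + depth sin(2 pi f_resp t)) to
    emulate respiratory thorax movement, optional additive Gaussian noise at
    ``noise_snr_db`` (relative to the clean signal power) and optional
    sinusoidal baseline drift (amplitude mV, frequency Hz)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if np.any(np.diff(beat_times) <= 0):
        raise DomainError("beat times must be strictly increasing")
    if modulation_depth >= 1:
        raise InfeasibleConfigError("modulation depth must be < 1")
    rng = _rng(rng)
    n = int(np.ceil((beat_times[-1] + 0.5) * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for tb in beat_times:
        mod = 1.0 + modulation_depth * np.sin(2 * np.pi * resp_rate_hz * tb)
        for frac, off, width in _PQRST:
            amp = r_amplitude_mv * frac
            if abs(frac) == 1.0:
                amp *= mod
            lo = max(0, int((tb + off - 4 * width) * fs))
            hi = min(n, int((tb + off + 4 * width) * fs) + 1)
            seg = t[lo:hi]
            x[lo:hi] += amp * np.exp(-0.5 * ((seg - tb - off) / width) ** 2)
    if baseline_drift is not None:
        amp, f = baseline_drift
        x += amp * np.sin(2 * np.pi * f * t)
    if noise_snr_db is not None:
        p_sig = float(np.mean(x**2))
        sigma = np.sqrt(p_sig / 10 ** (noise_snr_db / 10.0))
        x = x + rng.normal(0.0, sigma, n)
    return WaveformRecord(channel="ECG", fs=fs, samples=x)


def generate_bp(
    beat_times: np.ndarray,
    sbp: np.ndarray,
    dbp: np.ndarray,
    fs: float = 200.0,
) -> WaveformRecord:
    """Synthetic finger-pressure waveform whose per-beat extrema match the
    prescribed SBP/DBP targets.

    Each beat is a cosine-interpolated pulse: diastolic trough 10 % into the
    beat, systolic peak 35 % into the beat, monotone decay to the next
    trough, so beat-window extraction recovers the targets within 1 mmHg.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if sbp.size != beat_times.size or dbp.size != beat_times.size:
        raise DomainError("one SBP/DBP target pair per beat is required")
    if np.any(dbp <= 0) or np.any(sbp <= dbp):
        raise DomainError("targets must satisfy SBP > DBP > 0 for every beat")
    nn = np.diff(beat_times)
    nn = np.concatenate([nn, nn[-1:]])
    # node sequence: trough (DBP_i), peak (SBP_i), trough (DBP_{i+1}), ...
    node_t, node_v = [beat_times[0]], [dbp[0]]
    for i, tb in enumerate(beat_times):
        node_t.append(tb + 0.10 * nn[i])
        node_v.append(dbp[i])
        node_t.append(tb + 0.35 * nn[i])
        node_v.append(sbp[i])
    node_t, node_v = np.asarray(node_t), np.asarray(node_v)
    n = int(np.ceil((beat_times[-1] + 0.6 * nn[-1]) * fs))
    t = np.arange(n) / fs
    idx = np.clip(np.searchsorted(node_t, t, side="right") - 1, 0, node_t.size - 2)
    t0, t1 = node_t[idx], node_t[idx + 1]
    v0, v1 = node_v[idx], node_v[idx + 1]
    u = np.clip((t - t0) / np.maximum(t1 - t0, 1e-9), 0.0, 1.0)
    x = v0 + (v1 - v0) * (1 - np.cos(np.pi * u)) / 2
    x[t >= node_t[-1]] = node_v[-1]
    return WaveformRecord(channel="BP", fs=fs, samples=x)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Multi-subject session-table generator configuration.

    Baseline means default to the reference cohort's BDC-7 values (CTRL
    column) per posture, with the printed between-subject SD split evenly
    between the subject intercept and the residual (intraclass correlation
    0.5).  Log-scale indices are generated additively on the log10 scale and
    stored in natural units.  ``effects`` maps
    (index, group, timepoint, posture) to an additive shift in the index's
    generation scale.
    """

    n_ctrl: int = 11
    n_train: int = 12
    indices: tuple[str, ...] = ("HR", "SV", "SBP", "DBP", "HF", "LF", "VLF",
                                "LF/HF", "DFA1", "DBP-LF", "EDR", "CO", "TPR")
    baseline_means: dict = field(default_factory=dict)
    subject_sd: dict = field(default_factory=dict)
    resid_sd: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    seed: int | None = DEFAULT_SEED

    def __post_init__(self) -> None:
        for idx in self.indices:
            if idx not in self.baseline_means:
                self.baseline_means[idx] = {
                    pos: reference_cohort.cell_mean(idx, "BDC-7", "CTRL", pos)
                    for pos in ("supine", "sitting")
                }
            sd = reference_cohort.cell_sd(idx, "BDC-7", "CTRL", "supine")
            self.subject_sd.setdefault(idx, sd / np.sqrt(2))
            self.resid_sd.setdefault(idx, sd / np.sqrt(2))
        for idx, sd in {**self.subject_sd, **self.resid_sd}.items():
            if sd < 0:
                raise DomainError(f"negative SD for {idx!r}")
        for key in self.effects:
            idx, group, tp, pos = key
            if idx not in self.indices or group not in ("CTRL", "TRAIN"):
                raise DomainError(f"effect key {key} does not match the design")
            if tp not in TIMEPOINTS or pos not in ("supine", "sitting"):
                raise DomainError(f"effect key {key} does not match the design")


def generate_cohort(
    config: CohortConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort session table plus its ground-truth effects.

    value = baseline mean (posture-specific) + subject intercept + configured
    fixed effect + residual noise, on the log10 scale for frequency-domain
    indices.  Returns (session table, truth table); the truth table lists
    every non-zero injected effect in generation-scale units.
    """
    rng = _rng(rng if rng is not None else config.seed)
    subjects = [("CTRL", f"C{i+1:02d}") for i in range(config.n_ctrl)] + [
        ("TRAIN", f"T{i+1:02d}") for i in range(config.n_train)
    ]
    rows = []
    for idx in config.indices:
        log_scale = idx in LOG_INDICES
        for group, sid in subjects:
            b = rng.normal(0.0, config.subject_sd[idx])
            for tp, pos in SESSION_GRID:
                mu = config.baseline_means[idx][pos]
                eff = config.effects.get((idx, group, tp, pos), 0.0)
                v = mu + b + eff + rng.normal(0.0, config.resid_sd[idx])
                rows.append(
                    {
                        "subject": sid, "group": group, "timepoint": tp,
                        "posture": pos, "index": idx,
                        "value": float(10**v) if log_scale else float(v),
                    }
                )
    truth = pd.DataFrame(
        [
            {"index": k[0], "group": k[1], "timepoint": k[2], "posture": k[3],
             "effect": v}
            for k, v in config.effects.items()
            if v != 0.0
        ]
    )
    return pd.DataFrame(rows), truth


def simulate_timecourse_table(
    n_ctrl: int = 11,
    n_train: int = 12,
    sigma_subject: float = 5.0,
    sigma_resid: float = 5.0,
    baseline_mean: float = 100.0,
    effects: dict | None = None,
    index: str = "HR",
    rng=None,
) -> pd.DataFrame:
    """Normalized-scale time-course table (supine, follow-up timepoints) for
    inference calibration studies: value = 100 + subject intercept +
    effect(group, timepoint) + noise."""
    rng = _rng(rng)
    effects = effects or {}
    rows = []
    followups = [tp for tp in TIMEPOINTS if tp != "BDC-7"]
    subjects = [("CTRL", f"C{i+1:02d}") for i in range(n_ctrl)] + [
        ("TRAIN", f"T{i+1:02d}") for i in range(n_train)
    ]
    for group, sid in subjects:
        b = rng.normal(0.0, sigma_subject)
        for tp in followups:
            v = baseline_mean + b + effects.get((group, tp), 0.0) + rng.normal(
                0.0, sigma_resid
            )
            rows.append(
                {"subject": sid, "group": group, "timepoint": tp,
                 "posture": "supine", "index": index, "value": v}
            )
    return pd.DataFrame(rows)


def simulate_delta_table(
    n_ctrl: int = 11,
    n_train: int = 12,
    sigma_subject: float = 5.0,
    sigma_resid: float = 5.0,
    effects: dict | None = None,
    index: str = "TPR",
    rng=None,
) -> pd.DataFrame:
    """Postural-test delta-score table (both postures) for calibration
    studies: delta = subject intercept + effect(group, posture) + noise."""
    rng = _rng(rng)
    effects = effects or {}
    rows = []
    subjects = [("CTRL", f"C{i+1:02d}") for i in range(n_ctrl)] + [
        ("TRAIN", f"T{i+1:02d}") for i in range(n_train)
    ]
    for group, sid in subjects:
        b = rng.normal(0.0, sigma_subject)
        for pos in ("supine", "sitting"):
            d = b + effects.get((group, pos), 0.0) + rng.normal(0.0, sigma_resid)
            rows.append(
                {"subject": sid, "group": group, "posture": pos,
                 "index": index, "delta": d}
            )
    return pd.DataFrame(rows)
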