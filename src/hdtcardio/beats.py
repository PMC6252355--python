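"""Waveform ingest, R-peak detection, artifact rules and beat-series assembly.

The central object is :class:`BeatSeries`: per-beat event times with labels
(``normal`` / ``artifact`` / ``premature``) and per-beat systolic/diastolic
pressure, stroke volume and QRS amplitude.  Only beats labelled ``normal``
contribute to the normal-to-normal (N-N) interval series used downstream.

Manual expert editing of the recordings is replaced by an explicit,
configurable rule set (:class:`CleaningPolicy`): intervals outside physiologic
bounds or deviating from an 11-beat local median by more than a relative
threshold mark the corresponding beats, and a recording with more than 20 % of
its intervals invalidated is rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import (
    DomainError,
    InsufficientDataError,
    QualityFailureError,
    UnprocessableSignalError,
)

LABEL_NORMAL = "normal"
LABEL_ARTIFACT = "artifact"
LABEL_PREMATURE = "premature"

_BEAT_CSV_COLUMNS = ["time_s", "nn_ms", "label", "sbp_mmHg", "dbp_mmHg", "sv_mL", "qrs_mV"]


@dataclass
class WaveformRecord:
    """A single uniformly sampled channel (ECG in mV or BP in mmHg)."""

    channel: str
    fs: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DomainError(f"sampling rate must be > 0, got {self.fs}")
        if self.samples.size < 2:
            raise DomainError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise UnprocessableSignalError(
                f"channel {self.channel!r} contains non-finite samples"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """Per-beat event times and values; the pipeline's central container.

    ``nn_ms`` holds successive time differences in ms (one per beat after the
    first); an interval only enters the normal-to-normal series when both of
    its endpoint beats are labelled normal and the interval itself passed the
    cleaning rules (see :meth:`nn_intervals`).
    """

    times: np.ndarray
    labels: np.ndarray | None = None
    sbp: np.ndarray | None = None
    dbp: np.ndarray | None = None
    sv: np.ndarray | None = None
    qrs_amplitude: np.ndarray | None = None
    # intervals invalidated by cleaning even though neither endpoint beat was
    # individually ectopic (e.g. an isolated missed-beat gap)
    excluded_intervals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        if n < 2:
            raise InsufficientDataError("a beat series needs at least 2 beats")
        if not np.all(np.diff(self.times) > 0):
            raise DomainError("beat times must be strictly increasing")
        if self.labels is None:
            self.labels = np.full(n, LABEL_NORMAL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.excluded_intervals is None:
            self.excluded_intervals = np.zeros(n - 1, dtype=bool)
        else:
            self.excluded_intervals = np.asarray(self.excluded_intervals, dtype=bool)
        for name in ("sbp", "dbp", "sv", "qrs_amplitude"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise DomainError(f"{name} length {v.size} != beat count {n}")
                setattr(self, name, v)
        ok = (self.labels == LABEL_NORMAL)
        if self.sbp is not None and self.dbp is not None:
            both = ok & np.isfinite(self.sbp) & np.isfinite(self.dbp)
            if np.any(self.sbp[both] <= self.dbp[both]) or np.any(self.dbp[both] <= 0):
                raise DomainError("retained beats must satisfy SBP > DBP > 0")

    def __len__(self) -> int:
        return self.times.size

    @property
    def nn_ms(self) -> np.ndarray:
        """All successive intervals in ms, attributed to the later beat."""
        return np.diff(self.times) * 1000.0

    def valid_interval_mask(self) -> np.ndarray:
        """Intervals whose both endpoint beats are normal and which were not
        individually excluded by cleaning."""
        ok = self.labels == LABEL_NORMAL
        return ok[:-1] & ok[1:] & ~self.excluded_intervals

    def nn_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times of later beat, N-N interval ms) for valid intervals."""
        m = self.valid_interval_mask()
        return self.times[1:][m], self.nn_ms[m]

    def beat_values(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) of ``name`` for beats labelled normal with a
        finite value."""
        v = getattr(self, {"sbp": "sbp", "dbp": "dbp", "sv": "sv", "qrs": "qrs_amplitude"}[name])
        if v is None:
            raise DomainError(f"beat series has no {name!r} values")
        m = (self.labels == LABEL_NORMAL) & np.isfinite(v)
        return self.times[m], v[m]


@dataclass(frozen=True)
class CleaningPolicy:
    """Automatic artifact rules replacing manual beat editing.

    Defaults follow common HRV practice: physiologic interval bounds
    300–2000 ms, a 25 % jump threshold against the 11-beat local median, and
    drop mode (invalid intervals are excluded, not filled).
    """

    min_interval_ms: float = 300.0
    max_interval_ms: float = 2000.0
    jump_threshold: float = 0.25
    median_window: int = 11
    mode: str = "drop"  # or "interpolate"
    max_flagged_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not self.min_interval_ms < self.max_interval_ms:
            raise DomainError("interval bounds must be ordered")
        if not 0 < self.jump_threshold <= 1:
            raise DomainError("jump threshold must lie in (0, 1]")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise DomainError("median window must be odd and >= 3")
        if self.mode not in ("drop", "interpolate"):
            raise DomainError(f"unknown replacement mode {self.mode!r}")


def _local_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with shrinking windows at the edges."""
    n = x.size
    h = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = np.median(x[lo:hi])
    return out


def clean_beats(beats: BeatSeries, policy: CleaningPolicy | None = None) -> BeatSeries:
    """Label artifact/premature beats and invalidate deviant intervals.

    An interval is deviant when it violates the physiologic bounds or deviates
    from the local median interval by more than the jump threshold.  A beat
    flanked by two deviant intervals (the classic short-then-compensatory
    ectopic signature) is labelled ``premature`` (short first interval) or
    ``artifact``; an isolated deviant interval is excluded from the N-N series
    without condemning either endpoint beat.  Labels already present on the
    input are never overwritten.  The operation is idempotent: the flags are a
    deterministic function of the beat times.
    """
    policy = policy or CleaningPolicy()
    if len(beats) < 30:
        raise InsufficientDataError(f"need >= 30 beats, got {len(beats)}")
    nn = beats.nn_ms
    med = _local_median(nn, policy.median_window)
    deviant = (
        (nn < policy.min_interval_ms)
        | (nn > policy.max_interval_ms)
        | (np.abs(nn - med) > policy.jump_threshold * med)
    )
    labels = beats.labels.copy()
    n = len(beats)
    # beat i sits between interval i-1 and interval i
    for i in range(1, n - 1):
        if deviant[i - 1] and deviant[i] and labels[i] == LABEL_NORMAL:
            short = nn[i - 1] < med[i - 1]
            labels[i] = LABEL_PREMATURE if short else LABEL_ARTIFACT
    ok = labels == LABEL_NORMAL
    excluded = (deviant | beats.excluded_intervals) & ok[:-1] & ok[1:]
    invalid = ~(ok[:-1] & ok[1:] & ~excluded)
    if invalid.mean() > policy.max_flagged_fraction:
        raise QualityFailureError(
            f"{invalid.mean():.0%} of intervals invalid exceeds "
            f"{policy.max_flagged_fraction:.0%}; recording rejected"
        )
    return replace(beats, labels=labels, excluded_intervals=excluded)


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: WaveformRecord) -> np.ndarray:
    """Detect R-wave times (s) in a single-lead ECG.

    Band-pass (5–25 Hz) energy envelope with an adaptive threshold selects
    candidate complexes; each candidate is refined to the local maximum of the
    raw signal so reported times coincide with R-wave maxima within one
    sample.
    """
    if ecg.duration < 60:
        raise InsufficientDataError(
            f"ECG duration {ecg.duration:.1f} s < 60 s minimum"
        )
    if ecg.fs < 100:
        raise DomainError(f"sampling rate {ecg.fs} Hz < 100 Hz minimum")
    x = ecg.samples
    if np.ptp(x) == 0 or np.std(x) < 1e-12:
        raise UnprocessableSignalError("flat ECG signal")
    sos = _sig.butter(2, [5.0, 25.0], btype="bandpass", fs=ecg.fs, output="sos")
    f = _sig.sosfiltfilt(sos, x)
    env = _sig.convolve(f**2, np.ones(int(0.12 * ecg.fs)) / int(0.12 * ecg.fs), mode="same")
    refractory = int(0.25 * ecg.fs)
    cand, _ = _sig.find_peaks(env, distance=refractory)
    if cand.size == 0:
        raise UnprocessableSignalError("no QRS-like activity found")
    heights = env[cand]
    thr = 0.15 * np.median(heights[heights >= np.percentile(heights, 50)])
    cand = cand[heights > thr]
    half = int(0.10 * ecg.fs)
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        if 0 < p < x.size - 1 and x[p] >= x[p - 1] and x[p] >= x[p + 1]:
            peaks.append(p)
    peaks = np.unique(peaks)
    if peaks.size:  # enforce refractory separation after refinement
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] >= refractory:
                keep.append(p)
            elif x[p] > x[keep[-1]]:
                keep[-1] = p
        peaks = np.asarray(keep)
    if peaks.size < 30:
        raise InsufficientDataError(f"only {peaks.size} beats detected (< 30)")
    return ecg.start_time + peaks / ecg.fs


# ---------------------------------------------------------------------------
# Beat-wise BP and QRS amplitude extraction
# ---------------------------------------------------------------------------

def extract_beat_bp(
    bp: WaveformRecord, beat_times: np.ndarray, search_fraction: float = 0.6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract per-beat systolic and diastolic pressure.

    SBP_i is the maximum of the pressure wave in the window
    (t_i, t_i + ``search_fraction`` x local N-N]; the systolic peak trails the
    R wave by the pulse-transit delay, so the window opens at the beat.  DBP_i
    is the minimum preceding that maximum within the same window.  A
    non-pulsatile (flat) window flags the beat instead of producing values.

    Returns (sbp, dbp, artifact_mask); flagged beats carry NaN.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    t0 = bp.start_time
    t_end = t0 + bp.duration
    if beat_times[0] < t0 - 1e-9 or beat_times[-1] > t_end + 1e-9:
        raise DomainError("beat times fall outside the BP record span")
    nn = np.diff(beat_times)
    local_nn = np.concatenate([nn, nn[-1:]])
    sbp = np.full(beat_times.size, np.nan)
    dbp = np.full(beat_times.size, np.nan)
    artifact = np.zeros(beat_times.size, dtype=bool)
    for i, t in enumerate(beat_times):
        lo = int(np.ceil((t - t0) * bp.fs)) + 1
        hi = int(np.floor((t - t0 + search_fraction * local_nn[i]) * bp.fs)) + 1
        hi = min(hi, bp.samples.size)
        seg = bp.samples[lo:hi]
        if seg.size < 3 or np.ptp(seg) < 1.0:
            artifact[i] = True
            continue
        k = int(np.argmax(seg))
        s = seg[k]
        d = np.min(seg[: k + 1])
        if s <= d:
            artifact[i] = True
            continue
        sbp[i], dbp[i] = s, d
    return sbp, dbp, artifact


def extract_qrs_amplitudes(
    ecg: WaveformRecord,
    beat_times: np.ndarray,
    baseline_window: tuple[float, float] = (-0.14, -0.06),
) -> np.ndarray:
    """Per-beat QRS amplitude: R-peak value minus the local isoelectric level.

    The baseline is the median of a short pre-QRS segment (default 140–60 ms
    before the R wave), which tracks slow baseline drift without being
    contaminated by the P wave.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    idx = np.round((beat_times - ecg.start_time) * ecg.fs).astype(int)
    idx = np.clip(idx, 1, ecg.samples.size - 2)
    amps = np.empty(beat_times.size)
    w0 = int(round(baseline_window[0] * ecg.fs))
    w1 = int(round(baseline_window[1] * ecg.fs))
    for i, k in enumerate(idx):
        lo, hi = max(0, k - 2), min(ecg.samples.size, k + 3)
        p = lo + int(np.argmax(ecg.samples[lo:hi]))
        b_lo, b_hi = max(0, k + w0), max(1, k + w1)
        baseline = np.median(ecg.samples[b_lo:b_hi]) if b_hi > b_lo else 0.0
        amps[i] = ecg.samples[p] - baseline
    return amps


def assemble_beat_series(
    ecg: WaveformRecord,
    bp: WaveformRecord | None = None,
    policy: CleaningPolicy | None = None,
) -> BeatSeries:
    """Full ingest: detect beats, extract per-beat BP and QRS amplitude, and
    apply the cleaning policy."""
    t = detect_r_peaks(ecg)
    qrs = extract_qrs_amplitudes(ecg, t)
    sbp = dbp = None
    labels = np.full(t.size, LABEL_NORMAL, dtype=object)
    if bp is not None:
        sbp, dbp, art = extract_beat_bp(bp, t)
        labels[art] = LABEL_ARTIFACT
    beats = BeatSeries(times=t, labels=labels, sbp=sbp, dbp=dbp, qrs_amplitude=qrs)
    return clean_beats(beats, policy)


# ---------------------------------------------------------------------------
# Tabular and waveform I/O
# ---------------------------------------------------------------------------

def write_beat_csv(beats: BeatSeries, path: str | Path) -> None:
    """Write the beat table in the pipeline's CSV dialect.

    Columns: time_s, nn_ms, label, sbp_mmHg, dbp_mmHg, sv_mL, qrs_mV.  The
    first row's nn_ms is empty (intervals attach to the later beat).  Floats
    round-trip exactly (shortest-repr formatting).
    """
    n = len(beats)
    nn = np.concatenate([[np.nan], beats.nn_ms])
    cols = {
        "time_s": beats.times,
        "nn_ms": nn,
        "label": beats.labels,
        "sbp_mmHg": beats.sbp if beats.sbp is not None else np.full(n, np.nan),
        "dbp_mmHg": beats.dbp if beats.dbp is not None else np.full(n, np.nan),
        "sv_mL": beats.sv if beats.sv is not None else np.full(n, np.nan),
        "qrs_mV": beats.qrs_amplitude if beats.qrs_amplitude is not None else np.full(n, np.nan),
    }
    pd.DataFrame(cols).to_csv(path, index=False)


def read_beat_csv(path: str | Path) -> BeatSeries:
    """Read a beat table written by :func:`write_beat_csv` (or hand-made in
    the same dialect)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _BEAT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"beat CSV missing columns {missing}")

    def col(name: str) -> np.ndarray | None:
        v = df[name].to_numpy(dtype=float)
        return None if np.all(np.isnan(v)) else v

    return BeatSeries(
        times=df["time_s"].to_numpy(dtype=float),
        labels=df["label"].astype(str).to_numpy(dtype=object),
        sbp=col("sbp_mmHg"),
        dbp=col("dbp_mmHg"),
        sv=col("sv_mL"),
        qrs_amplitude=col("qrs_mV"),
    )


def read_waveform_csv(path: str | Path, channel: str = "signal") -> WaveformRecord:
    """Read a two-column waveform CSV (time_s, value) with a uniform grid."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "value"} <= set(df.columns):
        raise DomainError("waveform CSV needs columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.ptp(dt) > 1e-6 * dt[0]:
        raise DomainError("waveform CSV must be uniformly sampled")
    return WaveformRecord(
        channel=channel,
        fs=1.0 / dt[0],
        samples=df["value"].to_numpy(dtype=float),
        start_time=t[0],
    )


def write_waveform_csv(rec: WaveformRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.times, "value": rec.samples}).to_csv(path, index=False)


def read_wfdb_record(header_path: str | Path) -> list[WaveformRecord]:
    """Minimal reader for a WFDB-style header + 16-bit signal file pair.

    Supports single-segment records with format 16 (little-endian int16,
    sample-interleaved), per-signal gain and baseline.  Enough for the
    record+annotation pairs this pipeline accepts; not a general WFDB
    implementation.
    """
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_name, n_sig, fs, *_ = lines[0].split()
    n_sig = int(n_sig)
    fs = float(fs.split("/")[0])
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0]
        if fmt != "16":
            raise DomainError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        gain = 200.0
        baseline = 0.0
        if len(parts) > 2:
            g = parts[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = float(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        desc = parts[-1] if len(parts) > 8 else f"sig{len(specs)}"
        specs.append((fname, gain, baseline, desc))
    raw = np.fromfile(header_path.with_name(specs[0][0]), dtype="<i2")
    raw = raw.reshape(-1, n_sig)
    out = []
    for j, (_, gain, baseline, desc) in enumerate(specs):
        out.append(
            WaveformRecord(channel=desc, fs=fs, samples=(raw[:, j] - baseline) / gain)
        )
    return out
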