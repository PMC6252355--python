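import numpy as np
import pytest

import hdtcardio as hc
from hdtcardio.errors import (
    DomainError,
    InsufficientDataError,
    QualityFailureError,
    UnprocessableSignalError,
)


class TestDetectRPeaks:
    def test_periodic_ecg_recovers_one_hz_beats(self):
        ecg = hc.generate_ecg(np.arange(600, dtype=float) + 0.2)
        t = hc.detect_r_peaks(ecg)
        assert abs(len(t) - 600) <= 1
        spacing = np.diff(t)
        assert np.all(np.abs(spacing - 1.0) <= 0.005)

    def test_ipfm_beats_matched_within_one_sample(self, ipfm_recording):
        truth = ipfm_recording["beat_times"]
        det = hc.detect_r_peaks(ipfm_recording["ecg"])
        nearest = np.abs(truth[:, None] - det[None, :]).min(axis=1)
        sensitivity = np.mean(nearest <= 0.005)
        false_pos = np.sum(np.abs(det[:, None] - truth[None, :]).min(axis=1) > 0.005)
        assert sensitivity >= 0.995
        assert false_pos == 0

    def test_reported_times_are_local_maxima(self, ipfm_recording):
        ecg = ipfm_recording["ecg"]
        det = hc.detect_r_peaks(ecg)
        idx = np.round(det * ecg.fs).astype(int)
        assert np.all(ecg.samples[idx] >= ecg.samples[idx - 1])
        assert np.all(ecg.samples[idx] >= ecg.samples[idx + 1])

    def test_flat_signal_is_unprocessable(self):
        rec = hc.WaveformRecord("ECG", 200.0, np.zeros(200 * 120))
        with pytest.raises(UnprocessableSignalError):
            hc.detect_r_peaks(rec)

    def test_short_recording_rejected(self):
        ecg = hc.generate_ecg(np.arange(30, dtype=float))
        short = hc.WaveformRecord("ECG", 200.0, ecg.samples[: 200 * 40])
        with pytest.raises(InsufficientDataError):
            hc.detect_r_peaks(short)


class TestCleanBeats:
    def test_clean_series_untouched(self, constant_beats):
        out = hc.clean_beats(constant_beats)
        assert np.all(out.labels == "normal")
        assert not out.excluded_intervals.any()
        assert out.valid_interval_mask().all()

    def test_single_ectopic_pair_flags_exactly_two_intervals(self):
        t = list(np.arange(600, dtype=float))
        t.insert(300, 299.0 + 0.4)  # extra beat 400 ms after beat 299
        beats = hc.BeatSeries(times=np.array(t))
        out = hc.clean_beats(beats)
        assert np.sum(out.labels != "normal") == 1
        assert out.labels[300] == "premature"
        _, nn = out.nn_intervals()
        assert np.sum(~out.valid_interval_mask()) == 2
        assert nn.mean() == pytest.approx(1000.0, abs=1e-9)

    def test_heavily_corrupted_recording_rejected(self, rng):
        t = [0.0]
        for i in range(400):
            t.append(t[-1] + 1.0)
            if rng.random() < 0.25:
                t.append(t[-1] + 0.3)
        with pytest.raises(QualityFailureError):
            hc.clean_beats(hc.BeatSeries(times=np.array(t)))

    def test_idempotent(self):
        t = list(np.arange(200, dtype=float))
        t.insert(100, 99.0 + 0.35)
        beats = hc.BeatSeries(times=np.array(t))
        once = hc.clean_beats(beats)
        twice = hc.clean_beats(once)
        assert np.array_equal(once.labels, twice.labels)
        assert np.array_equal(once.excluded_intervals, twice.excluded_intervals)

    def test_existing_labels_never_overwritten(self, constant_beats):
        labels = constant_beats.labels.copy()
        labels[10] = "artifact"
        beats = hc.BeatSeries(times=constant_beats.times, labels=labels)
        out = hc.clean_beats(beats)
        assert out.labels[10] == "artifact"

    def test_policy_validation(self):
        with pytest.raises(DomainError):
            hc.CleaningPolicy(median_window=4)
        with pytest.raises(DomainError):
            hc.CleaningPolicy(jump_threshold=0.0)


class TestExtractBeatBp:
    def test_constant_pressure_targets_recovered(self):
        t = np.arange(60, dtype=float)
        bp = hc.generate_bp(t, np.full(60, 120.0), np.full(60, 80.0))
        sbp, dbp, art = hc.extract_beat_bp(bp, t[:-1])
        assert not art.any()
        assert np.all(np.abs(sbp - 120.0) <= 0.5)
        assert np.all(np.abs(dbp - 80.0) <= 0.5)

    def test_systolic_ramp_tracked(self):
        t = np.arange(60, dtype=float)
        target = np.linspace(110.0, 130.0, 60)
        bp = hc.generate_bp(t, target, np.full(60, 70.0))
        sbp, _, art = hc.extract_beat_bp(bp, t[:-1])
        assert not art.any()
        assert np.all(np.diff(sbp) > -1e-9)
        assert abs(sbp[0] - target[0]) <= 1.0
        assert abs(sbp[-2] - target[-2]) <= 1.0

    def test_flat_window_flags_only_that_beat(self):
        t = np.arange(60, dtype=float)
        bp = hc.generate_bp(t, np.full(60, 120.0), np.full(60, 80.0))
        fs = int(bp.fs)
        bp.samples[30 * fs : 31 * fs] = 0.0
        sbp, dbp, art = hc.extract_beat_bp(bp, t[:-1])
        assert art[30]
        assert not art[29] and not art[31]
        assert np.isnan(sbp[30])

    def test_beats_outside_span_rejected(self):
        t = np.arange(60, dtype=float)
        bp = hc.generate_bp(t, np.full(60, 120.0), np.full(60, 80.0))
        with pytest.raises(DomainError):
            hc.extract_beat_bp(bp, np.array([100.0, 200.0]))


class TestExtractQrsAmplitudes:
    def test_constant_amplitude_stable_within_one_percent(self):
        t = np.arange(120, dtype=float) + 0.5
        ecg = hc.generate_ecg(t, r_amplitude_mv=1.4)
        amps = hc.extract_qrs_amplitudes(ecg, t)
        assert amps.size == t.size
        assert np.ptp(amps[1:-1]) / np.mean(amps[1:-1]) < 0.01

    def test_baseline_drift_changes_amplitudes_below_two_percent(self):
        t = np.arange(120, dtype=float) + 0.5
        clean = hc.generate_ecg(t, r_amplitude_mv=1.4)
        drift = hc.generate_ecg(t, r_amplitude_mv=1.4, baseline_drift=(0.5, 0.05))
        a0 = hc.extract_qrs_amplitudes(clean, t)[1:-1]
        a1 = hc.extract_qrs_amplitudes(drift, t)[1:-1]
        assert np.max(np.abs(a1 - a0) / a0) < 0.02


class TestBeatSeriesInvariants:
    def test_nn_matches_time_differences(self, ipfm_recording):
        beats = hc.BeatSeries(times=ipfm_recording["beat_times"])
        assert np.allclose(beats.nn_ms, np.diff(beats.times) * 1000.0, atol=1e-6)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(DomainError):
            hc.BeatSeries(times=np.array([0.0, 1.0, 0.5]))

    def test_sbp_must_exceed_dbp(self):
        with pytest.raises(DomainError):
            hc.BeatSeries(
                times=np.arange(3.0),
                sbp=np.array([120.0, 70.0, 120.0]),
                dbp=np.array([80.0, 80.0, 80.0]),
            )


class TestIo:
    def test_beat_csv_round_trip_identical(self, tmp_path, ipfm_recording):
        t = ipfm_recording["beat_times"][:100]
        rng = np.random.default_rng(0)
        beats = hc.BeatSeries(
            times=t,
            sbp=120 + rng.normal(0, 5, t.size),
            dbp=80 + rng.normal(0, 3, t.size),
            qrs_amplitude=1.4 + rng.normal(0, 0.05, t.size),
        )
        path = tmp_path / "beats.csv"
        hc.write_beat_csv(beats, path)
        back = hc.read_beat_csv(path)
        assert np.array_equal(back.times, beats.times)
        assert np.array_equal(back.labels, beats.labels)
        for f in ("sbp", "dbp", "qrs_amplitude"):
            assert np.array_equal(getattr(back, f), getattr(beats, f))
        assert back.sv is None

    def test_waveform_csv_round_trip(self, tmp_path):
        rec = hc.generate_ecg(np.arange(70, dtype=float))
        path = tmp_path / "ecg.csv"
        hc.write_waveform_csv(rec, path)
        back = hc.read_waveform_csv(path, channel="ECG")
        assert back.fs == pytest.approx(rec.fs, rel=1e-9)
        assert np.allclose(back.samples, rec.samples)

    def test_minimal_wfdb_format16_reader(self, tmp_path):
        fs, gain = 200, 1000.0
        sig = np.sin(2 * np.pi * 1.3 * np.arange(fs * 5) / fs)
        raw = np.round(sig * gain).astype("<i2")
        (tmp_path / "rec.hea").write_text(
            f"rec 1 {fs} {raw.size}\nrec.dat 16 {gain:.0f}(0)/mV 16 0 0 0 0 ECG\n"
        )
        raw.tofile(tmp_path / "rec.dat")
        rec = hc.read_wfdb_record(tmp_path / "rec.hea")[0]
        assert rec.fs == fs
        assert np.max(np.abs(rec.samples - sig)) < 1e-3
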