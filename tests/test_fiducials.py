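import numpy as np
import pytest

from respifuse import (
    NoBeatsError,
    PipelineConfig,
    SyntheticConfig,
    detect_ppg_troughs,
    generate_ecg,
    generate_ppg,
    locate_q_waves,
    locate_systolic_peaks,
    pan_tompkins_rpeaks,
    preprocess,
)


def _match(detected, truth, fs, tol_s, interior=None):
    """Greedy one-to-one matching; returns (tp, fp, fn, |dt| list).

    *interior* restricts both detections and truth to [lo, hi] seconds so
    that beats straddling the window edges are scored on neither side.
    """
    det_t = np.asarray(detected, dtype=float) / fs
    if interior is not None:
        det_t = _interior(det_t, *interior)
        truth = _interior(truth, *interior)
    used = np.zeros(len(truth), dtype=bool)
    tp, dts = 0, []
    for d in det_t:
        i = np.argmin(np.abs(truth - d))
        if not used[i] and abs(truth[i] - d) <= tol_s:
            used[i] = True
            tp += 1
            dts.append(abs(truth[i] - d))
    return tp, len(det_t) - tp, len(truth) - tp, dts


def _interior(times, lo, hi):
    times = np.asarray(times)
    return times[(times >= lo) & (times <= hi)]


class TestPanTompkins:
    def test_clean_60bpm_count_and_timing(self, cfg):
        scfg = SyntheticConfig(duration=30.0, hr_bpm=60.0, rr_bpm=15.0,
                               noise_snr_db=np.inf, seed=3)
        ch, beats = generate_ecg(scfg)
        ecg = preprocess(ch.samples, ch.fs, cfg)
        r = pan_tompkins_rpeaks(ecg, ch.fs)
        assert abs(len(r) - 30) <= 1
        tp, fp, fn, dts = _match(r, beats, ch.fs, tol_s=0.010, interior=(0.3, 29.7))
        assert fn == 0 and fp <= 1
        assert max(dts) <= 0.010

    def test_flat_signal_raises(self):
        with pytest.raises(NoBeatsError):
            pan_tompkins_rpeaks(np.zeros(3000), 300.0)

    def test_20db_snr_sensitivity_and_ppv(self, cfg):
        tp = fp = fn = 0
        for seed in (1, 2, 3):
            scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=15.0,
                                   noise_snr_db=20.0, seed=seed)
            ch, beats = generate_ecg(scfg)
            ecg = preprocess(ch.samples, ch.fs, cfg)
            r = pan_tompkins_rpeaks(ecg, ch.fs)
            a, b, c, _ = _match(r, beats, ch.fs, tol_s=0.05,
                                interior=(0.3, scfg.duration - 0.3))
            tp, fp, fn = tp + a, fp + b, fn + c
        assert tp / (tp + fn) >= 0.99  # sensitivity
        assert tp / (tp + fp) >= 0.99  # positive predictivity

    @pytest.mark.parametrize("hr", [50, 70, 90, 120])
    def test_noise_free_f1_across_heart_rates(self, hr, cfg):
        scfg = SyntheticConfig(duration=30.0, hr_bpm=float(hr), rr_bpm=12.0,
                               noise_snr_db=np.inf, seed=5)
        ch, beats = generate_ecg(scfg)
        ecg = preprocess(ch.samples, ch.fs, cfg)
        r = pan_tompkins_rpeaks(ecg, ch.fs)
        tp, fp, fn, _ = _match(r, beats, ch.fs, tol_s=0.02, interior=(0.3, 29.7))
        assert fp == 0 and fn == 0  # F1 = 1.0

    def test_detected_intervals_within_physiologic_bounds(self, noisy_record, cfg):
        rec, _, _ = noisy_record
        ch = rec.get("ecg")
        r = pan_tompkins_rpeaks(preprocess(ch.samples, ch.fs, cfg), ch.fs)
        ibi = np.diff(r) / ch.fs
        assert np.all((ibi >= 0.3) & (ibi <= 2.0))


class TestQWaves:
    def test_dip_before_r_found(self):
        fs = 300.0
        ecg = np.zeros(3000)
        r_peaks = np.array([900, 1800, 2700])
        for r in r_peaks:
            ecg[r] = 1.0
            dip = r - int(0.080 * fs)  # V-shaped dip 80 ms before R
            ecg[dip - 3 : dip + 4] = -np.array([0.1, 0.3, 0.6, 0.8, 0.6, 0.3, 0.1])
        q, r = locate_q_waves(ecg, r_peaks, fs)
        np.testing.assert_array_equal(q, r_peaks - int(0.080 * fs))

    def test_monotone_ramp_gives_left_edge(self):
        fs = 300.0
        ecg = np.arange(3000, dtype=float)
        q, r = locate_q_waves(ecg, np.array([1500]), fs)
        assert q[0] == 1500 - int(0.2 * fs)

    def test_beat_too_close_to_window_start_dropped(self):
        q, r = locate_q_waves(np.zeros(3000), np.array([10, 1500]), 300.0)
        assert len(r) == 1 and r[0] == 1500


class TestPpgTroughs:
    def test_clean_75bpm_count_and_timing(self, cfg):
        scfg = SyntheticConfig(duration=30.0, hr_bpm=75.0, rr_bpm=15.0,
                               noise_snr_db=np.inf, seed=9)
        ch, onsets, _ = generate_ppg(scfg)
        ppg = preprocess(ch.samples, ch.fs, cfg)
        tr = detect_ppg_troughs(ppg, ch.fs)
        assert len(tr) in (36, 37, 38)
        tp, fp, fn, dts = _match(tr, onsets, ch.fs, tol_s=0.020, interior=(0.5, 29.5))
        assert fn == 0 and fp == 0
        assert max(dts) <= 0.020

    def test_constant_signal_raises(self):
        with pytest.raises(NoBeatsError):
            detect_ppg_troughs(np.ones(3000), 300.0)

    def test_missing_pulse_reduces_count_by_one(self, cfg):
        scfg = SyntheticConfig(duration=30.0, hr_bpm=75.0, rr_bpm=15.0,
                               noise_snr_db=np.inf, seed=9)
        ch, onsets, _ = generate_ppg(scfg)
        full = detect_ppg_troughs(preprocess(ch.samples, ch.fs, cfg), ch.fs)
        # excise one mid-record pulse by flattening its cycle
        k = len(onsets) // 2
        i0 = int(onsets[k] * ch.fs)
        i1 = int(onsets[k + 1] * ch.fs)
        x = ch.samples.copy()
        x[i0:i1] = x[i0]
        gap = detect_ppg_troughs(preprocess(x, ch.fs, cfg), ch.fs)
        assert len(gap) == len(full) - 1


class TestSystolicPeaks:
    def test_gaussian_pulse_apex_found(self):
        fs = 300.0
        t = np.arange(3000) / fs
        trough = 900
        apex_t = trough / fs + 0.060
        ppg = np.exp(-0.5 * ((t - apex_t) / 0.015) ** 2)
        ppg[: trough + 1] = 0.0
        peaks, troughs = locate_systolic_peaks(ppg, np.array([trough]), fs)
        assert abs(peaks[0] - int(apex_t * fs)) <= 1

    def test_decreasing_segment_gives_first_sample(self):
        fs = 300.0
        ppg = -np.arange(3000, dtype=float)
        peaks, _ = locate_systolic_peaks(ppg, np.array([600]), fs)
        assert peaks[0] == 601

    def test_trough_at_window_end_dropped(self):
        fs = 300.0
        ppg = np.zeros(3000)
        peaks, troughs = locate_systolic_peaks(ppg, np.array([600, 2999]), fs)
        assert len(troughs) == 1 and troughs[0] == 600


class TestPairingInvariants:
    def test_fiducial_set_invariants_on_synthetic(self, noisy_record, cfg):
        from respifuse import detect_fiducials

        rec, _, _ = noisy_record
        ecg, ppg = rec.get("ecg"), rec.get("ppg")
        fid = detect_fiducials(
            preprocess(ecg.samples, ecg.fs, cfg),
            preprocess(ppg.samples, ppg.fs, cfg),
            ecg.fs,
        )
        fid.validate()
        assert len(fid.r_peaks) > 0 and len(fid.ppg_troughs) > 0
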