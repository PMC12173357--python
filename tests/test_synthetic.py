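import numpy as np
import pytest

from respifuse import (
    PipelineConfig,
    SyntheticConfig,
    extract_ecg_rmcs,
    extract_ppg_rmcs,
    detect_fiducials,
    generate_beat_times,
    generate_ecg,
    generate_ppg,
    generate_record,
    preprocess,
    resample_beat_series,
)
from respifuse.errors import ConfigurationError
from respifuse.vmd import power_spectrum


def _peak(values, fs):
    f, p = power_spectrum(values, fs)
    return f[1:][np.argmax(p[1:])]


class TestBeatTimes:
    def test_unmodulated_metronome(self):
        scfg = SyntheticConfig(duration=10.0, hr_bpm=60.0, fm_depth=0.0,
                               rr_bpm=15.0, seed=0)
        beats = generate_beat_times(scfg)
        np.testing.assert_allclose(beats, np.arange(11.0))

    def test_beat_count_at_75_bpm(self):
        scfg = SyntheticConfig(duration=30.0, hr_bpm=75.0, fm_depth=0.0,
                               rr_bpm=15.0, seed=0)
        assert len(generate_beat_times(scfg)) in (37, 38)

    def test_rsa_peak_in_interval_series(self, cfg):
        scfg = SyntheticConfig(duration=120.0, hr_bpm=70.0, rr_bpm=15.0,
                               fm_depth=0.05, seed=1)
        beats = generate_beat_times(scfg)
        ibis = np.diff(beats)
        from respifuse import BeatSeries

        bs = BeatSeries("EFM", (beats[:-1] + beats[1:]) / 2, ibis)
        us = resample_beat_series(bs, cfg)
        assert _peak(us.values, us.fs) == pytest.approx(0.25, abs=0.02)

    def test_nyquist_violating_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(rr_bpm=42.0, hr_bpm=60.0)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(rr_bpm=30.0, hr_bpm=60.0)


class TestModulationIsolation:
    def _rmc_series(self, scfg, cfg):
        rec, truth = generate_record(scfg)
        ecg = preprocess(rec.get("ecg").samples, scfg.fs, cfg)
        ppg = preprocess(rec.get("ppg").samples, scfg.fs, cfg)
        fid = detect_fiducials(ecg, ppg, scfg.fs)
        eam, efm, ebw = extract_ecg_rmcs(ecg, fid, scfg.fs)
        pam, pfm, pbw = extract_ppg_rmcs(ppg, fid, scfg.fs)
        out = {}
        for bs in (eam, efm, ebw, pam, pfm, pbw):
            out[bs.component] = resample_beat_series(bs, cfg)
        return out

    def _peak_ratio(self, us, f_r):
        f, p = power_spectrum(us.values, us.fs)
        sel = np.abs(f - f_r) <= 0.03
        return p[sel].max() / np.median(p[1:])

    def test_no_modulation_gives_flat_components(self, cfg):
        scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=15.0,
                               am_depth=0.0, fm_depth=0.0, bw_amp=0.0,
                               ppg_am_depth=0.0, ppg_bw_amp=0.0,
                               noise_snr_db=np.inf, seed=3)
        series = self._rmc_series(scfg, cfg)
        # amplitude families: constant on interior beats, up to the slow
        # residual ripple the 0.05 Hz high-pass leaves on per-beat amplitudes
        for tag in ("EAM", "PAM"):
            assert np.ptp(series[tag].values[3:-3]) < 0.05, tag
        # baseline families measure the filtered baseline directly, which
        # carries the high-pass settling transient (below 0.05 Hz); flatness
        # here means: no spectral power concentrated at the breathing rate
        for tag in ("EBW", "PBW"):
            f, p = power_spectrum(series[tag].values, series[tag].fs)
            near_fr = np.abs(f - 0.25) <= 0.03
            assert p[near_fr].sum() / p[1:].sum() < 0.05, tag

    def test_ecg_amplitude_modulation_targets_eam(self, cfg):
        scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=18.0,
                               am_depth=0.2, fm_depth=0.0, bw_amp=0.0,
                               ppg_am_depth=0.0, ppg_bw_amp=0.0,
                               noise_snr_db=np.inf, seed=4)
        series = self._rmc_series(scfg, cfg)
        assert _peak(series["EAM"].values, series["EAM"].fs) == pytest.approx(0.30, abs=0.02)
        assert self._peak_ratio(series["EAM"], 0.30) > 5.0
        # the unmodulated amplitude family carries no tone at f_r
        assert abs(_peak(series["PAM"].values, series["PAM"].fs) - 0.30) > 0.05

    def test_ppg_amplitude_modulation_targets_pam(self, cfg):
        scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=12.0,
                               am_depth=0.0, fm_depth=0.0, bw_amp=0.0,
                               ppg_am_depth=0.3, ppg_bw_amp=0.0,
                               noise_snr_db=np.inf, seed=5)
        series = self._rmc_series(scfg, cfg)
        assert _peak(series["PAM"].values, series["PAM"].fs) == pytest.approx(0.20, abs=0.02)
        assert self._peak_ratio(series["PAM"], 0.20) > 5.0
        assert abs(_peak(series["EAM"].values, series["EAM"].fs) - 0.20) > 0.05

    def test_frequency_modulation_targets_interval_series(self, cfg):
        scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=15.0,
                               am_depth=0.0, fm_depth=0.05, bw_amp=0.0,
                               ppg_am_depth=0.0, ppg_bw_amp=0.0,
                               noise_snr_db=np.inf, seed=6)
        series = self._rmc_series(scfg, cfg)
        assert _peak(series["EFM"].values, series["EFM"].fs) == pytest.approx(0.25, abs=0.02)
        assert self._peak_ratio(series["EFM"], 0.25) > 5.0
        assert self._peak_ratio(series["PFM"], 0.25) > 5.0  # shared beat process

    def test_baseline_wander_targets_bw_series(self, cfg):
        scfg = SyntheticConfig(duration=60.0, hr_bpm=75.0, rr_bpm=15.0,
                               am_depth=0.0, fm_depth=0.0, bw_amp=0.15,
                               ppg_am_depth=0.0, ppg_bw_amp=0.15,
                               noise_snr_db=np.inf, seed=7)
        series = self._rmc_series(scfg, cfg)
        for tag in ("EBW", "PBW"):
            assert self._peak_ratio(series[tag], 0.25) > 5.0, tag


class TestRecordBundle:
    def test_reference_respiration_peaks_at_rr(self):
        scfg = SyntheticConfig(duration=60.0, rr_bpm=15.0, seed=8)
        rec, _ = generate_record(scfg)
        resp = rec.get("resp")
        assert _peak(resp.samples, resp.fs) == pytest.approx(0.25, abs=0.01)

    def test_fixed_seed_reproducible(self):
        scfg = SyntheticConfig(duration=30.0, rr_bpm=12.0, seed=9)
        a, _ = generate_record(scfg)
        b, _ = generate_record(scfg)
        for label in ("ecg", "ppg", "resp", "rr_ref"):
            np.testing.assert_array_equal(a.get(label).samples, b.get(label).samples)

    def test_ground_truth_sizes_consistent(self):
        scfg = SyntheticConfig(duration=30.0, rr_bpm=12.0, seed=10)
        rec, truth = generate_record(scfg)
        assert len(truth.ppg_onsets) == len(truth.beat_times) - 1
        assert len(truth.ppg_peaks) == len(truth.ppg_onsets)

    def test_rr_chirp_reference_ramps(self):
        scfg = SyntheticConfig(duration=60.0, rr_bpm=10.0, rr_bpm_end=20.0, seed=11)
        rec, _ = generate_record(scfg)
        rr = rec.get("rr_ref").samples
        assert rr[0] == pytest.approx(10.0)
        assert rr[-1] == pytest.approx(20.0, abs=0.2)
        assert np.all(np.diff(rr) > 0)

    def test_snr_degradation_does_not_improve_error(self):
        # median |rr_est - rr_true| should not decrease as SNR worsens
        from respifuse import run_pipeline

        meds = []
        for snr in (30.0, 0.0):
            errs = []
            for seed in (1, 2):
                scfg = SyntheticConfig(duration=60.0, rr_bpm=15.0, hr_bpm=80.0,
                                       noise_snr_db=snr, seed=seed)
                rec, _ = generate_record(scfg)
                for e in run_pipeline(rec, PipelineConfig()):
                    if e.rr is not None:
                        errs.append(abs(e.rr - 15.0))
            meds.append(np.median(errs) if errs else np.inf)
        assert meds[1] >= meds[0] - 0.05
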