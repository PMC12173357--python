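"""Synthetic cardiorespiratory record generator.

Produces paired ECG and PPG waveforms whose respiratory modulations are
known exactly, so every pipeline stage can be validated against ground
truth. One shared beat-time process (integral pulse frequency modulation
with sinusoidal respiratory sinus arrhythmia) drives both channels, as in
physiology:

* beat period  T(t) = 60/hr + fm_depth * sin(2 pi f_r t)
* ECG: a fixed Gaussian P-QRS-T template per beat, QRS amplitude scaled by
  (1 + am_depth * sin(2 pi f_r t_beat)), plus sinusoidal baseline wander
  and white noise at a chosen SNR;
* PPG: each cardiac cycle renders a smooth rise/decay pulse (half-cosine
  up to the systolic peak ~12% into the cycle, half-cosine down to the
  next onset) delayed 0.2 s after the R wave, with analogous amplitude /
  interval / baseline modulation;
* reference respiration sin(2 pi f_r t) and a constant reference RR.

Breathing is sinusoidal at f_r = rr_bpm/60; a linear RR chirp mode
(``rr_bpm_end``) exercises time-varying-rate tracking. Fiducial ground
truth is exact by construction: R peaks at the beat times, Q waves 40 ms
earlier, PPG onsets (troughs) at beat time + 0.2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .signal_io import Channel, WaveformRecord

#: ECG template: (offset_s, sigma_s, amplitude); QRS entries are scaled by
#: the amplitude-modulation factor, P/T stay fixed
_ECG_QRS = ((-0.040, 0.008, -0.15), (0.0, 0.010, 1.0), (0.040, 0.008, -0.10))
_ECG_PT = ((-0.200, 0.025, 0.10), (0.250, 0.040, 0.20))

PPG_DELAY_S = 0.2  # pulse transit delay from R wave to pulse onset
PPG_PEAK_PHASE = 0.12  # systolic peak position as a fraction of the cycle
PPG_FOOT_DEPTH = 0.15  # depth of the pre-systolic foot notch
PPG_FOOT_WIDTH = 0.015  # notch width as a fraction of the cycle


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mimic a resting adult on a bedside
    monitor (8-minute record at 300 Hz, 80 bpm heart rate, 15 breaths/min,
    moderate modulation depths, 20 dB additive-noise SNR)."""

    duration: float = 480.0
    fs: float = 300.0
    hr_bpm: float = 80.0
    rr_bpm: float = 15.0
    rr_bpm_end: float | None = None  # linear RR chirp target (None = constant)
    am_depth: float = 0.2
    fm_depth: float = 0.05
    bw_amp: float = 0.1
    ppg_am_depth: float = 0.2
    ppg_fm_depth: float = 0.05
    ppg_bw_amp: float = 0.1
    noise_snr_db: float = 20.0
    beat_jitter_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rr in (self.rr_bpm, self.rr_bpm_end):
            if rr is None:
                continue
            if not (3.0 <= rr <= 45.0):
                raise ConfigurationError(f"rr_bpm={rr} outside [3, 45]")
            if not rr / 60.0 < self.hr_bpm / 120.0:
                raise ConfigurationError(
                    f"respiratory tone {rr / 60.0:.3f} Hz at or above the beat-"
                    f"sampling Nyquist {self.hr_bpm / 120.0:.3f} Hz (hr={self.hr_bpm})"
                )
        if not (40.0 <= self.hr_bpm <= 180.0):
            raise ConfigurationError(f"hr_bpm={self.hr_bpm} outside [40, 180]")
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigurationError("duration and fs must be positive")


def _resp_phase(cfg: SyntheticConfig, t: np.ndarray | float) -> np.ndarray | float:
    """Integrated respiratory phase (radians); linear chirp when rr_bpm_end
    is set, otherwise constant-rate."""
    f0 = cfg.rr_bpm / 60.0
    if cfg.rr_bpm_end is None:
        return 2 * np.pi * f0 * t
    f1 = cfg.rr_bpm_end / 60.0
    k = (f1 - f0) / cfg.duration
    return 2 * np.pi * (f0 * t + 0.5 * k * np.asarray(t) ** 2)


def _resp_sin(cfg: SyntheticConfig, t: np.ndarray | float) -> np.ndarray | float:
    return np.sin(_resp_phase(cfg, t))


def generate_beat_times(cfg: SyntheticConfig) -> np.ndarray:
    """Beat times from the instantaneous heart period
    T(t) = 60/hr + fm_depth * sin(phase(t)), iterated from t=0."""
    rng = np.random.default_rng(cfg.seed)
    base = 60.0 / cfg.hr_bpm
    times = [0.0]
    while True:
        t = times[-1]
        period = base + cfg.fm_depth * float(_resp_sin(cfg, t))
        if cfg.beat_jitter_s > 0:
            period += cfg.beat_jitter_s * rng.standard_normal()
        period = max(period, 0.3)
        nxt = t + period
        if nxt > cfg.duration:
            break
        times.append(nxt)
    return np.asarray(times)


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(snr_db):
        return x
    p_sig = float(np.mean((x - x.mean()) ** 2))
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    return x + sigma * rng.standard_normal(len(x))


def generate_ecg(
    cfg: SyntheticConfig, beat_times: np.ndarray | None = None
) -> tuple[Channel, np.ndarray]:
    """Render the ECG channel; returns (channel, ground-truth R times)."""
    if beat_times is None:
        beat_times = generate_beat_times(cfg)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    for tb in beat_times:
        factor = 1.0 + cfg.am_depth * float(_resp_sin(cfg, tb))
        for off, sig, amp in _ECG_QRS:
            _render_gauss(x, cfg.fs, tb + off, sig, amp * factor)
        for off, sig, amp in _ECG_PT:
            _render_gauss(x, cfg.fs, tb + off, sig, amp)
    x += cfg.bw_amp * _resp_sin(cfg, t)
    rng = np.random.default_rng(cfg.seed + 1)
    x = _add_noise(x, cfg.noise_snr_db, rng)
    return Channel(label="ecg", samples=x, fs=cfg.fs, units="mV"), beat_times


def _render_gauss(x: np.ndarray, fs: float, center: float, sigma: float, amp: float) -> None:
    lo = max(0, int(np.floor((center - 4 * sigma) * fs)))
    hi = min(len(x), int(np.ceil((center + 4 * sigma) * fs)) + 1)
    if lo >= hi:
        return
    tt = np.arange(lo, hi) / fs
    x[lo:hi] += amp * np.exp(-0.5 * ((tt - center) / sigma) ** 2)


def generate_ppg(
    cfg: SyntheticConfig, beat_times: np.ndarray | None = None
) -> tuple[Channel, np.ndarray, np.ndarray]:
    """Render the PPG channel.

    Returns (channel, ground-truth onset/trough times, systolic-peak times).
    Onsets trail the shared beat times by the pulse-transit delay; each
    cycle rises over the first PPG_PEAK_PHASE of the onset-to-onset
    interval and decays back to zero at the next onset, so the waveform
    minimum of a clean record sits exactly on each onset.
    """
    if beat_times is None:
        beat_times = generate_beat_times(cfg)
    onsets = beat_times + PPG_DELAY_S
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    peak_times = []
    for k in range(len(onsets) - 1):
        o0, o1 = onsets[k], onsets[k + 1]
        i0, i1 = int(np.ceil(o0 * cfg.fs)), min(n, int(np.ceil(o1 * cfg.fs)))
        if i0 >= i1:
            continue
        phase = (t[i0:i1] - o0) / (o1 - o0)
        amp = 1.0 + cfg.ppg_am_depth * float(_resp_sin(cfg, o0))
        rise = phase < PPG_PEAK_PHASE
        pulse = np.empty_like(phase)
        pulse[rise] = 0.5 * (1 - np.cos(np.pi * phase[rise] / PPG_PEAK_PHASE))
        pulse[~rise] = 0.5 * (
            1 + np.cos(np.pi * (phase[~rise] - PPG_PEAK_PHASE) / (1 - PPG_PEAK_PHASE))
        )
        # fixed-depth pre-systolic foot at the cycle boundary: makes the
        # waveform minimum sharply localized on the onset, as in the steep
        # diastolic-to-systolic transition of real pulses (unscaled, so the
        # waveform stays continuous across cycles of different amplitude)
        foot = -PPG_FOOT_DEPTH * (
            np.exp(-0.5 * (phase / PPG_FOOT_WIDTH) ** 2)
            + np.exp(-0.5 * ((phase - 1.0) / PPG_FOOT_WIDTH) ** 2)
        )
        x[i0:i1] += amp * pulse + foot
        peak_times.append(o0 + PPG_PEAK_PHASE * (o1 - o0))
    x += cfg.ppg_bw_amp * _resp_sin(cfg, t)
    rng = np.random.default_rng(cfg.seed + 2)
    x = _add_noise(x, cfg.noise_snr_db, rng)
    ch = Channel(label="ppg", samples=x, fs=cfg.fs, units="a.u.")
    return ch, onsets[:-1], np.asarray(peak_times)


@dataclass
class GroundTruth:
    beat_times: np.ndarray
    ppg_onsets: np.ndarray
    ppg_peaks: np.ndarray
    rr_bpm: float
    rr_bpm_end: float | None = None


def generate_record(cfg: SyntheticConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Bundle ECG, PPG, reference respiration and reference RR channels."""
    beats = generate_beat_times(cfg)
    ecg_ch, _ = generate_ecg(cfg, beats)
    ppg_ch, onsets, peaks = generate_ppg(cfg, beats)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    resp = Channel(label="resp", samples=np.asarray(_resp_sin(cfg, t)), fs=cfg.fs)
    t_rr = np.arange(int(cfg.duration))
    if cfg.rr_bpm_end is None:
        rr_vals = np.full(len(t_rr), cfg.rr_bpm, dtype=float)
    else:
        rr_vals = cfg.rr_bpm + (cfg.rr_bpm_end - cfg.rr_bpm) * t_rr / cfg.duration
    rr_ch = Channel(label="rr_ref", samples=rr_vals, fs=1.0)
    rec = WaveformRecord(
        channels=[ecg_ch, ppg_ch, resp, rr_ch],
        subject_id=f"synthetic_seed{cfg.seed}",
    )
    truth = GroundTruth(
        beat_times=beats, ppg_onsets=onsets, ppg_peaks=peaks,
        rr_bpm=cfg.rr_bpm, rr_bpm_end=cfg.rr_bpm_end,
    )
    return rec, truth
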