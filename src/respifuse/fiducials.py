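"""Beat-landmark detection on preprocessed ECG and PPG windows.

ECG R-peaks come from the Pan-Tompkins chain (5-15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive signal/noise thresholds
with a 200 ms refractory period), with each detection mapped back to the
local maximum of the raw ECG within +/-50 ms. The Q wave is the minimum in
the 200 ms interval preceding each R wave.

PPG pulse onsets (troughs) use an adaptive threshold: candidate local minima
separated by at least 300 ms are kept when they fall below a running 25th
percentile of the signal over a 2 s context. The systolic peak is the
maximum within 125 ms after each trough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import percentile_filter

from .errors import NoBeatsError

log = logging.getLogger(__name__)

#: physiologic inter-beat interval bounds (s); beats outside are rejected
IBI_BOUNDS = (0.3, 2.0)


@dataclass
class FiducialSet:
    """Per-window beat landmarks as 0-based sample indices.

    ``q_waves`` pairs one-to-one with ``r_peaks`` (each Q within 200 ms
    before its R); ``ppg_peaks`` pairs with ``ppg_troughs`` (each systolic
    peak within 125 ms after its trough).
    """

    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    q_waves: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ppg_troughs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ppg_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fs: float = 300.0

    def validate(self) -> None:
        for name in ("r_peaks", "q_waves", "ppg_troughs", "ppg_peaks"):
            idx = getattr(self, name)
            assert np.all(np.diff(idx) > 0), f"{name} not strictly increasing"
        assert len(self.q_waves) == len(self.r_peaks)
        assert len(self.ppg_peaks) == len(self.ppg_troughs)
        if len(self.r_peaks):
            d = (self.r_peaks - self.q_waves) / self.fs
            assert np.all((d > 0) & (d <= 0.2 + 1e-9))
        if len(self.ppg_troughs):
            d = (self.ppg_peaks - self.ppg_troughs) / self.fs
            assert np.all((d > 0) & (d <= 0.125 + 1e-9))


def _enforce_ibi(idx: np.ndarray, fs: float, what: str) -> np.ndarray:
    """Drop beats forming out-of-physiologic-range intervals (< 0.3 s)."""
    if len(idx) < 2:
        return idx
    keep = [int(idx[0])]
    for i in idx[1:]:
        if (i - keep[-1]) / fs >= IBI_BOUNDS[0]:
            keep.append(int(i))
        else:
            log.debug("%s: dropped beat at %d (interval < %.1fs)", what, i, IBI_BOUNDS[0])
    return np.asarray(keep, dtype=int)


def pan_tompkins_rpeaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Locate R-peaks with the Pan-Tompkins algorithm.

    Returns strictly increasing sample indices into *ecg*; raises
    :class:`NoBeatsError` if no beat is found.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) / fs < 2.0:
        raise NoBeatsError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        raise NoBeatsError("flat ECG signal")

    # band-pass 5-15 Hz (zero-phase, so no group-delay correction needed)
    sos = sps.butter(2, [5.0, 15.0], "bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refr = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refr)
    if len(cand) == 0:
        raise NoBeatsError("no candidate peaks in integrated signal")

    # adaptive signal/noise levels, initialized from the first 2 s
    init = mwi[: int(2 * fs)]
    spki = float(np.max(init)) * 0.5
    npki = float(np.mean(init)) * 0.5
    peaks: list[int] = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] >= thr:
            peaks.append(int(c))
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki
    if not peaks:
        raise NoBeatsError("no peaks above adaptive threshold")

    # map each detection back to the raw-ECG local maximum within +/-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(ecg), p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    refined = _enforce_ibi(refined, fs, "ecg")
    if len(refined) == 0:
        raise NoBeatsError("no beats after refinement")
    return refined


def locate_q_waves(
    ecg: np.ndarray, r_peaks: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Find the Q wave (minimum within the 200 ms preceding each R).

    R-peaks whose 200 ms search interval extends before the window start are
    dropped. Returns ``(q_indices, retained_r_peaks)``.
    """
    ecg = np.asarray(ecg, dtype=float)
    span = int(np.floor(0.200 * fs))
    qs, rs = [], []
    for r in np.asarray(r_peaks, dtype=int):
        lo = r - span
        if lo < 0:
            log.debug("dropped beat at %d: Q search interval precedes window", r)
            continue
        seg = ecg[lo:r]
        if len(seg) == 0:
            continue
        qs.append(lo + int(np.argmin(seg)))
        rs.append(int(r))
    return np.asarray(qs, dtype=int), np.asarray(rs, dtype=int)


def detect_ppg_troughs(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Locate PPG pulse onsets (troughs) with an adaptive threshold.

    Candidate local minima (>= 300 ms apart) are retained when at or below
    the running 25th percentile of the signal over a 2 s sliding context.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) / fs < 2.0:
        raise NoBeatsError("need at least 2 s of PPG")
    if np.ptp(ppg) == 0:
        raise NoBeatsError("flat PPG signal")

    refr = int(round(0.300 * fs))
    cand, _ = sps.find_peaks(-ppg, distance=refr)
    if len(cand) == 0:
        raise NoBeatsError("no local minima in PPG")
    ctx = int(round(2.0 * fs)) | 1  # odd size, centered
    thr = percentile_filter(ppg, 25, size=ctx, mode="nearest")
    troughs = cand[ppg[cand] <= thr[cand] + 1e-12]
    if len(troughs) == 0:
        raise NoBeatsError("no PPG troughs below adaptive threshold")
    return _enforce_ibi(np.asarray(troughs, dtype=int), fs, "ppg")


def locate_systolic_peaks(
    ppg: np.ndarray, troughs: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Find the systolic peak (maximum within 125 ms after each trough).

    Troughs with no samples left before the window end are dropped with
    their pair. Returns ``(peak_indices, retained_troughs)``.
    """
    ppg = np.asarray(ppg, dtype=float)
    span = int(np.floor(0.125 * fs))  # floor keeps peak-trough lag <= 125 ms
    peaks, kept = [], []
    for t in np.asarray(troughs, dtype=int):
        lo, hi = t + 1, min(len(ppg), t + span + 1)
        if lo >= hi:
            log.debug("dropped trough at %d: no samples before window end", t)
            continue
        peaks.append(lo + int(np.argmax(ppg[lo:hi])))
        kept.append(int(t))
    return np.asarray(peaks, dtype=int), np.asarray(kept, dtype=int)


def detect_fiducials(ecg: np.ndarray, ppg: np.ndarray, fs: float) -> FiducialSet:
    """Run all four detectors on one window; channels that fail leave their
    fiducial arrays empty (the caller decides how to proceed)."""
    fid = FiducialSet(fs=fs)
    try:
        r = pan_tompkins_rpeaks(ecg, fs)
        q, r = locate_q_waves(ecg, r, fs)
        fid.q_waves, fid.r_peaks = q, r
    except NoBeatsError as e:
        log.debug("ECG fiducials failed: %s", e)
    try:
        tr = detect_ppg_troughs(ppg, fs)
        pk, tr = locate_systolic_peaks(ppg, tr, fs)
        fid.ppg_peaks, fid.ppg_troughs = pk, tr
    except NoBeatsError as e:
        log.debug("PPG fiducials failed: %s", e)
    return fid
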