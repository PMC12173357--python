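"""Respiratory modulated component (RMC) extraction.

Six beat-domain series carry respiratory information:

========  ======================================================  =========
tag       definition                                              units
========  ======================================================  =========
EAM       R minus Q amplitude per cardiac cycle                   signal
EFM       interval between successive R-peaks (RSA)               seconds
EBW       mean of R and Q amplitudes per cycle                    signal
PAM       systolic peak minus pulse-onset amplitude per cycle     signal
PFM       interval between successive systolic peaks              seconds
PBW       midpoint of peak and onset amplitudes per cycle         signal
========  ======================================================  =========

Amplitude/baseline values are timestamped at the R-peak (ECG) or systolic
peak (PPG); interval values at the interval midpoint. Each irregular beat
series is then cubic-spline resampled onto a uniform grid (default 10 Hz)
and mean-subtracted, which the VMD and spectral stages require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .config import PipelineConfig
from .errors import InsufficientBeatsError
from .fiducials import FiducialSet

ECG_TAGS = ("EAM", "EFM", "EBW")
PPG_TAGS = ("PAM", "PFM", "PBW")
ALL_TAGS = ECG_TAGS + PPG_TAGS

MIN_BEATS = 4


@dataclass
class BeatSeries:
    """Irregularly sampled (time, value) respiratory modulation series."""

    component: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.component}: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class UniformSeries:
    """A beat series resampled to a uniform grid ``t0 + k/fs``, zero-mean."""

    component: str
    fs: float
    values: np.ndarray
    t0: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def __len__(self) -> int:
        return len(self.values)


def _check_beats(n: int, what: str) -> None:
    if n < MIN_BEATS:
        raise InsufficientBeatsError(f"{what}: {n} usable beats (< {MIN_BEATS})")


def extract_ecg_rmcs(
    ecg: np.ndarray, fid: FiducialSet, fs: float
) -> tuple[BeatSeries, BeatSeries, BeatSeries]:
    """Compute the EAM, EFM and EBW beat series from ECG fiducials."""
    ecg = np.asarray(ecg, dtype=float)
    r, q = fid.r_peaks, fid.q_waves
    _check_beats(len(r), "ECG")
    t_r = r / fs
    eam = BeatSeries("EAM", t_r, ecg[r] - ecg[q])
    ebw = BeatSeries("EBW", t_r, (ecg[r] + ecg[q]) / 2.0)
    efm = BeatSeries("EFM", (t_r[:-1] + t_r[1:]) / 2.0, np.diff(t_r))
    return eam, efm, ebw


def extract_ppg_rmcs(
    ppg: np.ndarray, fid: FiducialSet, fs: float
) -> tuple[BeatSeries, BeatSeries, BeatSeries]:
    """Compute the PAM, PFM and PBW beat series from PPG fiducials."""
    ppg = np.asarray(ppg, dtype=float)
    pk, tr = fid.ppg_peaks, fid.ppg_troughs
    _check_beats(len(pk), "PPG")
    t_p = pk / fs
    pam = BeatSeries("PAM", t_p, ppg[pk] - ppg[tr])
    pbw = BeatSeries("PBW", t_p, (ppg[pk] + ppg[tr]) / 2.0)
    pfm = BeatSeries("PFM", (t_p[:-1] + t_p[1:]) / 2.0, np.diff(t_p))
    return pam, pfm, pbw


def resample_beat_series(
    bs: BeatSeries,
    cfg: PipelineConfig | None = None,
    t0: float = 0.0,
    span: tuple[float, float] | None = None,
) -> UniformSeries:
    """Cubic-spline resample a beat series onto the uniform grid
    ``t0 + k/beat_series_fs``, restricted to the observed beat interval
    (no extrapolation), then mean-subtract.

    *span* optionally restricts the grid further (used by the pipeline to
    put all six components on one common grid).
    """
    cfg = cfg or PipelineConfig()
    _check_beats(len(bs), bs.component)
    fs = cfg.beat_series_fs
    lo, hi = bs.times[0], bs.times[-1]
    if span is not None:
        lo, hi = max(lo, span[0]), min(hi, span[1])
    k0 = int(np.ceil((lo - t0) * fs - 1e-9))
    k1 = int(np.floor((hi - t0) * fs + 1e-9))
    if k1 < k0:
        raise InsufficientBeatsError(f"{bs.component}: empty grid after restriction")
    grid = t0 + np.arange(k0, k1 + 1) / fs
    spline = CubicSpline(bs.times, bs.values)
    vals = spline(grid)
    vals = vals - vals.mean()
    return UniformSeries(component=bs.component, fs=fs, values=vals, t0=grid[0])
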