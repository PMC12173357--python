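"""Waveform I/O, windowing and preprocessing.

A record is a set of simultaneously sampled channels (ECG, PPG, optionally a
reference respiration trace and a reference RR series). On disk a record is
a directory of two-column CSV files, one per channel, header ``time,value``.
Channel labels are normalized to ``{ecg, ppg, resp, rr_ref}`` through a
configurable label map so that records exported from other systems (e.g.
``pleth`` for the PPG channel) load without renaming files.

Preprocessing follows the standard chain for respiratory-component
extraction: resample to a common 300 Hz rate, 10-point moving-average
smoothing against high-frequency noise, then a zero-phase third-order
Butterworth high-pass at 0.05 Hz against baseline drift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .config import PipelineConfig
from .errors import ChannelLabelError, DataError, ShortWindowError

#: filename-stem aliases -> normalized channel label
DEFAULT_LABEL_MAP: dict[str, str] = {
    "ecg": "ecg",
    "ekg": "ecg",
    "ii": "ecg",
    "ppg": "ppg",
    "pleth": "ppg",
    "resp": "resp",
    "respiration": "resp",
    "co2": "resp",
    "rr_ref": "rr_ref",
    "rr": "rr_ref",
}


@dataclass
class Channel:
    label: str
    samples: np.ndarray
    fs: float
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError(f"channel {self.label}: fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DataError(f"channel {self.label}: non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class WaveformRecord:
    """Multichannel sampled record with per-channel sampling rates."""

    channels: list[Channel]
    subject_id: str = ""

    def get(self, label: str) -> Channel:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise ChannelLabelError(f"record {self.subject_id!r} has no {label!r} channel")

    def has(self, label: str) -> bool:
        return any(ch.label == label for ch in self.channels)

    @property
    def duration(self) -> float:
        return min(ch.duration for ch in self.channels)


@dataclass
class AnalysisWindow:
    """One half-open analysis interval [start, start+length) with both
    waveform channels resampled to the pipeline's common rate."""

    start_time: float
    length: float
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    ref_rr: float | None = None
    resp: np.ndarray | None = None


# ---------------------------------------------------------------------------
# record I/O


def _infer_fs(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise DataError("time column must be strictly increasing")
    med = float(np.median(dt))
    if not np.allclose(dt, med, rtol=1e-3, atol=1e-6):
        raise DataError("time column is not uniformly sampled")
    return 1.0 / med


def load_record(
    path: str | Path,
    format: str = "csv",
    label_map: dict[str, str] | None = None,
    subject_id: str | None = None,
) -> WaveformRecord:
    """Load a waveform record.

    ``csv``: *path* is a directory of per-channel two-column CSV files
    (header ``time,value``); each file stem is resolved through *label_map*.
    A record must expose at least one ECG-like and one PPG-like channel.
    """
    if format == "wfdb":
        raise NotImplementedError(
            "WFDB reading is not available in this build; convert the record "
            "to per-channel CSV (header time,value) and use format='csv'"
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a record directory")
    lmap = {**DEFAULT_LABEL_MAP, **(label_map or {})}

    channels: list[Channel] = []
    seen: dict[str, Path] = {}
    for f in sorted(path.glob("*.csv")):
        stem = f.stem.lower()
        label = lmap.get(stem)
        if label is None:
            continue
        if label in seen:
            raise ChannelLabelError(
                f"ambiguous {label!r} channel: both {seen[label].name} and {f.name}"
            )
        seen[label] = f
        df = pd.read_csv(f)
        if list(df.columns[:2]) != ["time", "value"]:
            raise DataError(f"{f}: expected header time,value")
        t = df["time"].to_numpy(dtype=float)
        v = df["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise DataError(f"{f}: non-finite samples")
        if label == "rr_ref":
            # reference RR is a slow annotation series, not a waveform
            fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        else:
            fs = _infer_fs(t)
        channels.append(Channel(label=label, samples=v, fs=fs))

    labels = {c.label for c in channels}
    if "ecg" not in labels or "ppg" not in labels:
        raise ChannelLabelError(
            f"record {path} must contain ecg and ppg channels; found {sorted(labels)}"
        )
    return WaveformRecord(channels=channels, subject_id=subject_id or path.name)


def save_record(record: WaveformRecord, path: str | Path) -> Path:
    """Write a record as a directory of per-channel CSV files (round-trips
    through :func:`load_record`)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for ch in record.channels:
        t = np.arange(len(ch.samples)) / ch.fs
        pd.DataFrame({"time": t, "value": ch.samples}).to_csv(
            path / f"{ch.label}.csv", index=False
        )
    return path


# ---------------------------------------------------------------------------
# resampling and preprocessing


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited (polyphase) resampling from fs_in to fs_out."""
    if math.isclose(fs_in, fs_out):
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def preprocess(x: np.ndarray, fs: float, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Smooth and high-pass filter one window of signal.

    A centered ``smoothing_points`` moving average (reflective edges) removes
    high-frequency noise, then a zero-phase Butterworth high-pass removes
    baseline drift below ``highpass_cutoff_hz``. Zero-phase (forward-backward)
    application preserves fiducial timing; the effective attenuation is the
    squared magnitude response. Output has the same length as the input.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(x, dtype=float)
    sos = sps.butter(cfg.highpass_order, cfg.highpass_cutoff_hz, "highpass", fs=fs, output="sos")
    # sosfiltfilt needs a minimum padding length; anything shorter cannot be
    # filtered stably
    ntaps = 3 * (2 * cfg.highpass_order + 1)
    if len(x) <= max(ntaps, cfg.smoothing_points):
        raise ShortWindowError(f"window of {len(x)} samples too short to filter")
    smoothed = uniform_filter1d(x, size=cfg.smoothing_points, mode="reflect")
    return sps.sosfiltfilt(sos, smoothed)


def segment_windows(record: WaveformRecord, cfg: PipelineConfig) -> list[AnalysisWindow]:
    """Cut a record into sliding analysis windows.

    Windows start at ``k * step`` with ``step = window_length * step_fraction``;
    only fully contained windows are emitted, and within each window the ECG
    and PPG channels are resampled to ``cfg.target_fs``.
    """
    L = cfg.window_length_s
    step = L * cfg.step_fraction
    dur = record.duration
    if dur < L:
        warnings.warn(
            f"record {record.subject_id!r} shorter ({dur:.1f}s) than one window ({L}s)",
            stacklevel=2,
        )
        return []

    ecg_ch, ppg_ch = record.get("ecg"), record.get("ppg")
    # resample once at record level, then slice: cheaper and avoids per-window
    # filter edge effects from the resampler
    ecg_rs = resample_to(ecg_ch.samples, ecg_ch.fs, cfg.target_fs)
    ppg_rs = resample_to(ppg_ch.samples, ppg_ch.fs, cfg.target_fs)
    resp_ch = record.get("resp") if record.has("resp") else None
    rr_ch = record.get("rr_ref") if record.has("rr_ref") else None

    nwin = int(np.round(L * cfg.target_fs))
    out: list[AnalysisWindow] = []
    k = 0
    while k * step + L <= dur + 1e-9:
        start = k * step
        i0 = int(np.round(start * cfg.target_fs))
        if i0 + nwin > min(len(ecg_rs), len(ppg_rs)):
            break
        ref_rr = None
        if rr_ch is not None and len(rr_ch.samples):
            # reference RR for a window = mean annotation over its span
            t_rr = np.arange(len(rr_ch.samples)) / rr_ch.fs
            m = (t_rr >= start) & (t_rr < start + L)
            ref_rr = float(np.mean(rr_ch.samples[m])) if m.any() else float(
                rr_ch.samples[np.argmin(np.abs(t_rr - (start + L / 2)))]
            )
        resp = None
        if resp_ch is not None:
            j0 = int(np.round(start * resp_ch.fs))
            j1 = j0 + int(np.round(L * resp_ch.fs))
            if j1 <= len(resp_ch.samples):
                resp = resp_ch.samples[j0:j1]
        out.append(
            AnalysisWindow(
                start_time=start,
                length=L,
                fs=cfg.target_fs,
                ecg=ecg_rs[i0 : i0 + nwin],
                ppg=ppg_rs[i0 : i0 + nwin],
                ref_rr=ref_rr,
                resp=resp,
            )
        )
        k += 1
    return out
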