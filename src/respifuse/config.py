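"""Pipeline configuration.

All tunable parameters of the RR-estimation pipeline live in one dataclass
that round-trips through YAML. Defaults follow the published processing
chain: 30 s analysis windows, signals resampled to 300 Hz, a 10-point
smoother plus 0.05 Hz third-order high-pass, five VMD modes, and the
physiological respiratory band 0.05-0.75 Hz (3-45 breaths/min).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Parameters controlling every stage of the RR pipeline.

    Attributes
    ----------
    window_length_s:
        Analysis window length in seconds (30-60 s is the sensible range;
        longer windows blur RR variation, shorter ones lose spectral
        resolution).
    step_fraction:
        Sliding-step as a fraction of the window length; 1.0 means
        non-overlapping windows.
    target_fs:
        Common sampling rate (Hz) both raw channels are resampled to.
    smoothing_points:
        Length of the moving-average smoother applied after resampling.
    highpass_cutoff_hz, highpass_order:
        Butterworth high-pass removing baseline drift below the
        respiratory band.
    vmd_K:
        Number of VMD modes used to denoise each respiratory component.
    vmd_alpha, vmd_tau, vmd_tol:
        VMD bandwidth penalty, dual-ascent step and convergence tolerance.
    resp_band_hz:
        Physiological respiratory band (low, high) in Hz.
    beat_series_fs:
        Uniform resampling rate (Hz) for the beat-domain component series.
    normalize_rmcs:
        Scale each component to unit variance before PCA fusion, so that
        interval series (seconds) and amplitude series (arbitrary units)
        contribute comparably.
    seed:
        Seed for any stochastic stage (none of the core stages are random;
        kept for reproducibility of optional debug sampling).
    """

    window_length_s: float = 30.0
    step_fraction: float = 1.0
    target_fs: float = 300.0
    smoothing_points: int = 10
    highpass_cutoff_hz: float = 0.05
    highpass_order: int = 3
    vmd_K: int = 5
    vmd_alpha: float = 2000.0
    vmd_tau: float = 0.0
    vmd_tol: float = 1e-7
    resp_band_hz: tuple[float, float] = (0.05, 0.75)
    beat_series_fs: float = 10.0
    normalize_rmcs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.resp_band_hz = tuple(self.resp_band_hz)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        low, high = self.resp_band_hz
        if not (0 < low < high < self.target_fs / 2):
            raise ConfigurationError(
                f"respiratory band {self.resp_band_hz} must satisfy "
                f"0 < low < high < target_fs/2 = {self.target_fs / 2}"
            )
        if not (30.0 <= self.window_length_s <= 60.0):
            raise ConfigurationError(
                f"window_length_s={self.window_length_s} outside [30, 60]"
            )
        if not (0 < self.step_fraction <= 1.0):
            raise ConfigurationError(
                f"step_fraction={self.step_fraction} outside (0, 1]"
            )
        if self.step_fraction * self.window_length_s < 1.0 / self.beat_series_fs:
            raise ConfigurationError("sliding step shorter than one beat-series sample")
        if self.vmd_K < 1:
            raise ConfigurationError("vmd_K must be >= 1")
        if self.target_fs <= 0 or self.beat_series_fs <= 0:
            raise ConfigurationError("sampling rates must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resp_band_hz"] = list(self.resp_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
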