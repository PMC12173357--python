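"""Respiratory quality index (RQI) and adaptive component screening.

The RQI of a component is the fraction of its spectral power falling inside
the physiological respiratory band (0.05-0.75 Hz, i.e. 3-45 breaths/min):

    RQI = P_band / P_total,

where both sums run over the magnitude-squared Fourier coefficients of the
raw (unwindowed, unpadded) series; the zero-frequency bin is excluded from
the total since components are mean-subtracted upstream. RQI is 1 for a
pure in-band tone and 0 for a purely out-of-band signal.

Per analysis window, the mean RQI of the available components serves as an
adaptive threshold T; every component with RQI >= T is kept for fusion. The
maximum is never below the mean, so at least one component always survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, ShortWindowError
from .vmd import FilteredRMC


@dataclass
class RQIReport:
    """Per-window RQI values, adaptive threshold and selection mask.

    ``rqi_values`` is keyed by component tag; components a window failed to
    extract are simply absent (they contribute to neither the mean nor the
    selection).
    """

    rqi_values: dict[str, float]
    threshold_T: float
    selected: dict[str, bool]

    @property
    def m(self) -> int:
        return sum(self.selected.values())


def compute_rqi(x: np.ndarray, fs: float, band: tuple[float, float] = (0.05, 0.75)) -> float:
    """Spectral-concentration RQI of a zero-mean series, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise ShortWindowError(f"series of {len(x)} samples too short for RQI")
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    p_all = float(power[1:].sum())  # exclude DC bin
    if p_all == 0.0:
        return 0.0
    eps = 1e-12
    in_band = (freqs >= band[0] - eps) & (freqs <= band[1] + eps)
    in_band[0] = False
    return float(power[in_band].sum() / p_all)


def adaptive_threshold_select(rqis: dict[str, float]) -> tuple[float, dict[str, bool]]:
    """Mean-threshold selection rule: T = mean of the available RQIs,
    keep every component with RQI >= T (never empty, since max >= mean)."""
    if not rqis:
        raise DegenerateSignalError("no RQI values to threshold")
    T = float(np.mean(list(rqis.values())))
    return T, {tag: bool(v >= T) for tag, v in rqis.items()}


def screen_components(
    filtered: dict[str, FilteredRMC],
    fs: float,
    band: tuple[float, float] = (0.05, 0.75),
) -> RQIReport:
    """Score the available filtered components and select those with
    RQI at or above the adaptive mean threshold."""
    if not filtered:
        raise DegenerateSignalError("no components available to screen")
    rqis = {tag: compute_rqi(f.values, fs, band) for tag, f in filtered.items()}
    T, selected = adaptive_threshold_select(rqis)
    return RQIReport(rqi_values=rqis, threshold_T=T, selected=selected)
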