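"""Error metrics and Bland-Altman agreement for RR estimates.

Given paired estimated and reference RR series (breaths/min), with
d_i = RR_est(i) - RR_ref(i):

    ME   = mean(d)                       (bias)
    STD  = sample standard deviation of d   (n-1 denominator)
    MAE  = mean(|d|)
    RMSE = sqrt(mean(d^2))

Bland-Altman agreement reports the bias and the 95% limits of agreement
ME +/- 1.96 * STD. The algebraic identity RMSE^2 = ME^2 + STD^2 (n-1)/n
ties the four metrics together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass
class ErrorSummary:
    me: float
    std: float
    mae: float
    rmse: float
    n: int
    ba_bias: float
    ba_loa: tuple[float, float]
    n_excluded: int = 0  # pairs dropped for a missing estimate or reference


def error_metrics(rr_est, rr_ref) -> ErrorSummary:
    """Compute ME/STD/MAE/RMSE and Bland-Altman limits for paired series.

    Pairs where either value is missing (NaN) are excluded and counted in
    ``n_excluded``. Requires at least two complete pairs.
    """
    est = np.asarray(rr_est, dtype=float)
    ref = np.asarray(rr_ref, dtype=float)
    if est.shape != ref.shape:
        raise DataError(f"length mismatch: {est.shape} vs {ref.shape}")
    ok = np.isfinite(est) & np.isfinite(ref)
    n_excluded = int((~ok).sum())
    d = est[ok] - ref[ok]
    n = len(d)
    if n < 2:
        raise DataError(f"need >= 2 complete pairs, got {n}")
    me = float(np.mean(d))
    std = float(np.std(d, ddof=1))
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d**2)))
    loa = (me - 1.96 * std, me + 1.96 * std)
    return ErrorSummary(
        me=me, std=std, mae=mae, rmse=rmse, n=n,
        ba_bias=me, ba_loa=loa, n_excluded=n_excluded,
    )


def per_subject_then_pooled(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]]
) -> tuple[dict[str, ErrorSummary], ErrorSummary]:
    """Per-record metrics plus pooled metrics over all window pairs.

    *pairs* maps subject id -> (rr_est, rr_ref). The pooled summary
    concatenates every record's pairs; both conventions are returned so a
    cohort can be reported either way.
    """
    if not pairs:
        raise DataError("no records to evaluate")
    per: dict[str, ErrorSummary] = {}
    all_est, all_ref = [], []
    for sid, (est, ref) in pairs.items():
        per[sid] = error_metrics(est, ref)
        all_est.append(np.asarray(est, dtype=float))
        all_ref.append(np.asarray(ref, dtype=float))
    pooled = error_metrics(np.concatenate(all_est), np.concatenate(all_ref))
    return per, pooled
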