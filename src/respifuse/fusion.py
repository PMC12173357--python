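"""Time-domain fusion of the selected respiratory components via PCA.

The m selected components (on a common uniform grid) form the columns of a
matrix X. After column centering (and, by default, unit-variance scaling so
that interval series in seconds and amplitude series in arbitrary units
contribute comparably), the covariance matrix of the columns is
eigen-decomposed and X is projected onto the leading eigenvector:

    RW_est = X_c . q_1,

the fused respiratory waveform. Its dominant spectral peak is the RR
estimate's input. The projection sign is fixed so the largest-magnitude
loading is positive (PCA sign is otherwise arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError
from .rmc import UniformSeries


@dataclass
class FusedWaveform:
    values: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: float
    component_tags: tuple[str, ...]


def fuse_components(
    rmcs: list[UniformSeries], normalize: bool = True
) -> FusedWaveform:
    """Project m components on a common grid onto their first principal
    component.

    All series must share length and grid. Raises
    :class:`DegenerateSignalError` when every column is constant.
    """
    if not rmcs:
        raise DegenerateSignalError("no components to fuse")
    L = len(rmcs[0])
    if any(len(s) != L for s in rmcs):
        raise ValueError("all components must share one grid length")
    if L < 32:
        raise DegenerateSignalError(f"common grid of {L} samples too short")

    X = np.column_stack([s.values for s in rmcs]).astype(float)
    X = X - X.mean(axis=0)
    stds = X.std(axis=0)
    if np.all(stds == 0):
        raise DegenerateSignalError("all components are constant")
    if normalize:
        nz = stds > 0
        X[:, nz] = X[:, nz] / stds[nz]

    P = (X.T @ X) / (L - 1)  # covariance of the (centered) columns
    evals, evecs = np.linalg.eigh(P)
    order = np.argsort(-evals, kind="stable")  # descending, ties keep order
    evals, evecs = evals[order], evecs[:, order]
    q = evecs[:, 0]
    if q[np.argmax(np.abs(q))] < 0:
        q = -q
    values = X @ q
    total = float(evals.sum())
    evr = float(evals[0] / total) if total > 0 else 0.0
    return FusedWaveform(
        values=values,
        loadings=q,
        explained_variance_ratio=evr,
        component_tags=tuple(s.component for s in rmcs),
    )
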