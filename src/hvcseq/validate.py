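"""Matching fitted factorizations against planted ground truth.

Convolutional factorizations carry a time-shift ambiguity — a fitted
exemplar may be a shifted copy of the planted one with its timecourse
shifted oppositely — and multiplicative updates smear occurrence mass over
adjacent bins. Matching therefore smooths both timecourses (boxcar of width
2L - 1, as in the consistency analysis) and maximizes the correlation over
lags up to one exemplar length before greedily assigning fitted factors to
planted ones.
"""

from __future__ import annotations

import numpy as np

from .containers import Factorization
from .convnmf import _smooth_rows
from .synth import SynthGroundTruth


def _best_lag_corr(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Max Pearson correlation of a with circularly lagged b over |lag| <= max_lag."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        best = max(best, float(az @ np.roll(bz, lag)) / a.size)
    return best


def occurrence_time_correlation(
    f: Factorization,
    gt: SynthGroundTruth,
    smooth_width: int | None = None,
) -> np.ndarray:
    """Per planted factor: correlation between its occurrence-time indicator
    and the best-matching fitted timecourse (greedy assignment)."""
    K_true = gt.true_W.shape[1]
    T = f.T
    width = smooth_width if smooth_width is not None else 2 * f.Lbins - 1
    Hs = _smooth_rows(f.H, width)
    inds = np.stack(
        [gt.occurrence_indicator(k, T) for k in range(K_true)]
    )
    inds = _smooth_rows(inds, width)
    C = np.zeros((K_true, f.K))
    for k in range(K_true):
        for j in range(f.K):
            C[k, j] = _best_lag_corr(inds[k], Hs[j], f.Lbins)
    out = np.zeros(K_true)
    Cw = C.copy()
    for _ in range(min(K_true, f.K)):
        k, j = np.unravel_index(np.argmax(Cw), Cw.shape)
        out[k] = C[k, j]
        Cw[k, :] = -np.inf
        Cw[:, j] = -np.inf
    return out
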