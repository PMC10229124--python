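"""Preprocessing: AR-2 deconvolution and amplitude renormalization.

Calcium-indicator fluorescence is modelled per neuron as an AR-2 process
driven by non-negative neural events plus white observation noise:

    y_t = c_t + e_t,   c_t = g1 * c_{t-1} + g2 * c_{t-2} + s_t,   s_t >= 0.

The deconvolution parameters (g1, g2 and the noise floor) are estimated
per neuron; events are recovered by inverting the AR-2 dynamics; and the
resulting event-rate matrix is renormalized so that neurons with large
transients (e.g. from high indicator expression) are given some priority in
the factorization, but not much more than weakly expressing neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter, periodogram, welch

from .containers import TraceMatrix


@dataclass
class Ar2Params:
    """Per-neuron AR-2 deconvolution parameters."""

    gamma1: float
    gamma2: float
    noise_floor: float
    valid: bool = True  # False for constant/degenerate traces


def _noise_sd_highfreq(y: np.ndarray, fs: float) -> float:
    """Noise sd from the average PSD above fs/4, where the slow calcium
    kernel contributes little power (one-sided PSD of white noise of
    variance s^2 is flat at 2 s^2 / fs)."""
    freqs, psd = welch(y, fs=fs, nperseg=min(256, y.size))
    hi = freqs > fs / 4.0
    return float(np.sqrt(np.mean(psd[hi]) * fs / 2.0)) if hi.any() else 0.0


def estimate_ar2(trace: np.ndarray, frame_rate: float) -> Ar2Params:
    """Estimate AR-2 coefficients and the noise floor of one trace.

    The observation model is an AR-2 process driven by (sparse) events plus
    white noise; its power spectrum is ``S(w) = ss / |1 - g1 e^{-iw} -
    g2 e^{-2iw}|^2 + sn``. Both AR poles (parametrized inside the unit
    circle, so the estimate is stable by construction), the drive variance
    and the noise variance are fit to the periodogram by minimizing the
    Whittle likelihood. For a pure white-noise trace the AR part collapses
    and the noise floor approaches the sample sd. Constant traces are
    flagged invalid (excluded downstream).
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 100:
        raise ValueError("need at least 100 bins to estimate AR-2 parameters")
    if np.ptp(y) == 0:
        return Ar2Params(0.0, 0.0, 0.0, valid=False)

    yc = y - y.mean()
    freqs, I = periodogram(yc, fs=frame_rate)
    freqs, I = freqs[1:], I[1:]  # drop DC
    w = 2.0 * np.pi * freqs / frame_rate
    e1 = np.exp(-1j * w)
    e2 = np.exp(-2j * w)
    scale = 2.0 / frame_rate  # one-sided periodogram of variance-v noise ~ 2v/fs
    v = yc.var()

    def nll(th):
        p1 = 1.0 / (1.0 + np.exp(-th[0]))
        p2 = 1.0 / (1.0 + np.exp(-th[1]))
        g1, g2 = p1 + p2, -p1 * p2
        ss = np.exp(th[2])
        sn = np.exp(th[3])
        S = ss / np.abs(1.0 - g1 * e1 - g2 * e2) ** 2 + sn
        return float(np.sum(np.log(S) + I / (S * scale)))

    th0 = np.array([np.log(9.0), 0.0, np.log(v * 0.05 + 1e-12),
                    np.log(v * 0.1 + 1e-12)])
    res = minimize(nll, th0, method="Nelder-Mead",
                   options=dict(maxiter=2000, xatol=1e-6, fatol=1e-8))
    p1 = 1.0 / (1.0 + np.exp(-res.x[0]))
    p2 = 1.0 / (1.0 + np.exp(-res.x[1]))
    noise_sd = float(np.sqrt(np.exp(res.x[3])))
    # Degenerate AR part (no temporal structure): report the broadband sd.
    if np.exp(res.x[2]) < 1e-6 * v:
        noise_sd = max(noise_sd, _noise_sd_highfreq(yc, frame_rate))
    return Ar2Params(float(p1 + p2), float(-p1 * p2), noise_sd, valid=True)


def deconvolve(
    trace: np.ndarray,
    params: Ar2Params,
    threshold_scale: float = 4.0,
    relative_floor: float = 0.03,
) -> np.ndarray:
    """Recover a non-negative event series from one trace.

    Applies the exact AR-2 inverse filter ``s_t = y_t - g1 y_{t-1} -
    g2 y_{t-2}``, clips at zero, and suppresses values below
    ``threshold_scale`` times the noise floor propagated through the inverse
    filter — this is where the noise floor controls sparsity. Reconvolving
    the result approximates the trace up to noise scale.
    """
    y = np.asarray(trace, dtype=float)
    if not params.valid:
        return np.zeros_like(y)
    g1, g2 = params.gamma1, params.gamma2
    raw = lfilter([1.0, -g1, -g2], [1.0], y)
    # Noise scale of the inverse-filtered series: the propagated spectral
    # estimate, guarded from below by a robust in-band estimate (events are
    # sparse outliers, so the MAD reflects the noise, not the signal).
    inv_gain = np.sqrt(1.0 + g1**2 + g2**2)
    robust = 1.4826 * float(np.median(np.abs(raw - np.median(raw))))
    noise_scale = max(params.noise_floor * inv_gain, robust)
    s = np.clip(raw, 0.0, None)
    if noise_scale > 0:
        s[s < threshold_scale * noise_scale] = 0.0
    if relative_floor > 0 and s.size:
        # Suppress sub-percent ringing left by small kernel-estimate errors
        # (visible when the noise floor is essentially zero).
        s[s < relative_floor * s.max()] = 0.0
    return s


def reconvolve(events: np.ndarray, params: Ar2Params) -> np.ndarray:
    """Forward AR-2 convolution of an event series (inverse of deconvolve)."""
    return lfilter([1.0], [1.0, -params.gamma1, -params.gamma2],
                   np.asarray(events, dtype=float))


def deconvolve_matrix(
    tm: TraceMatrix,
    params: list[Ar2Params] | None = None,
    threshold_scale: float = 4.0,
) -> tuple[TraceMatrix, list[Ar2Params]]:
    """Deconvolve every neuron, segment by segment (files are short,
    discontinuous recordings, so each is inverted independently)."""
    if params is None:
        params = [
            estimate_ar2(tm.values[n], tm.frame_rate_hz)
            for n in range(tm.n_neurons)
        ]
    out = np.zeros_like(tm.values)
    for n, p in enumerate(params):
        for s, e in tm.segment_bounds:
            out[n, s:e] = deconvolve(tm.values[n, s:e], p, threshold_scale)
    dtm = TraceMatrix(out, tm.frame_rate_hz, list(tm.segment_bounds),
                      list(tm.neuron_ids))
    return dtm, params


def renormalize(tm: TraceMatrix) -> TraceMatrix:
    """Equalize amplitudes across neurons.

    Each row is divided by (that row's maximum + the 95th percentile of the
    signal across all neurons and timebins, zeros included). Strongly
    expressing neurons keep some priority but not much more than weak ones.
    Scale-covariant: scaling the whole input by c > 0 leaves the output
    unchanged. Not idempotent.
    """
    X = tm.values
    if np.any(X < 0):
        raise ValueError("renormalize expects a non-negative (deconvolved) matrix")
    if not np.any(X):
        warnings.warn("all-zero matrix; renormalization returns it unchanged")
        return TraceMatrix(X.copy(), tm.frame_rate_hz, list(tm.segment_bounds),
                           list(tm.neuron_ids))
    global_p95 = float(np.percentile(X, 95))
    row_max = X.max(axis=1, keepdims=True)
    denom = row_max + global_p95
    denom[denom == 0] = 1.0  # all-zero rows pass through as zeros
    return TraceMatrix(X / denom, tm.frame_rate_hz, list(tm.segment_bounds),
                       list(tm.neuron_ids))


def preprocess_traces(
    tm: TraceMatrix,
    threshold_scale: float = 4.0,
) -> tuple[TraceMatrix, list[Ar2Params]]:
    """Full preprocessing: per-neuron AR-2 estimation, deconvolution, and
    amplitude renormalization — the matrix the factorization consumes."""
    dtm, params = deconvolve_matrix(tm, threshold_scale=threshold_scale)
    return renormalize(dtm), params
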