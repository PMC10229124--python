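"""Circular-shift significance testing for time-lagged cross-correlation,
and its three applications: neuron participation in sequences, song
locking, and factor autocorrelation.

The test compares the cross-correlation of two series at lags within
``[-L, L]`` against null cross-correlations obtained by circularly shifting
one series by random large lags (``L < |l| < T - L``). The significance
threshold is the ``100 * (1 - p / Num)``-th percentile of the absolute null
values, where ``Num = 2L x (number of tests being run)`` implements a
Bonferroni correction over the whole family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Factorization, SongFeatureMatrix, TraceMatrix


@dataclass
class XcorrResult:
    """Lag-indexed cross-correlation with its circular-shift null."""

    lags: np.ndarray  # integer bins in [-L, L]
    cc: np.ndarray  # cross-correlation per lag
    null_abs_quantile: float  # Bonferroni threshold value
    sig_mask: np.ndarray  # |cc| > threshold, per lag
    p: float
    num_comparisons: int

    @property
    def any_significant(self) -> bool:
        return bool(self.sig_mask.any())

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


def circular_xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full circular cross-correlation ``cc[l] = sum_t a[t] * b[(t+l) % T]``
    for l = 0..T-1 (negative lags wrap: cc(-l) = cc[T-l])."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    T = a.size
    return np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=T)


def circshift_xcorr_test(
    a: np.ndarray,
    b: np.ndarray,
    L: int,
    p: float = 0.05,
    num_tests: int = 1,
    two_sided: bool = True,
) -> XcorrResult:
    """Test which lags in [-L, L] show significant cross-correlation.

    Both series are zero-meaned internally. The null set is the circular
    cross-correlation at lags L < |l| < T - L; the threshold is the
    ``100 * (1 - p / Num)``-th percentile of |null| with ``Num = 2 * L *
    num_tests``. With ``two_sided=False`` the raw (signed) cc is compared to
    the same quantile of the signed null values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    T = a.size
    if T <= 2 * L:
        raise ValueError(f"series length {T} must exceed 2L = {2 * L}")
    ac = a - a.mean()
    bc = b - b.mean()
    cc_full = circular_xcorr(ac, bc)

    # Null lags: L < l < T - L (one copy of each |l| by circular periodicity).
    null = cc_full[L + 1 : T - L]
    num = max(1, int(round(2 * L * num_tests)))
    q = 100.0 * (1.0 - p / num)
    q = min(q, 100.0)
    if two_sided:
        threshold = float(np.percentile(np.abs(null), q))
    else:
        threshold = float(np.percentile(null, q))

    lags = np.arange(-L, L + 1)
    cc = cc_full[lags % T]
    sig = (np.abs(cc) if two_sided else cc) > threshold
    return XcorrResult(
        lags=lags, cc=cc, null_abs_quantile=threshold, sig_mask=sig,
        p=p, num_comparisons=num,
    )


# ---------------------------------------------------------------------------
# Application 1: which neurons participate in which sequences
# ---------------------------------------------------------------------------

def participation(
    X: TraceMatrix,
    f: Factorization,
    L_seconds: float = 0.5,
    p: float = 0.05,
    return_results: bool = False,
):
    """Neuron-by-factor participation via lagged cross-correlation.

    Neuron n participates in factor k iff its (deconvolved) trace has any
    significant lag against ``H[k]`` within +-L. Bonferroni family size is
    (2L bins) x (N neurons) x (K sequences) — 30 x N x K at the default
    0.5 s window and 30 Hz.

    Returns the boolean N x K matrix (and optionally the per-pair
    :class:`XcorrResult` grid).
    """
    L = int(round(L_seconds * X.frame_rate_hz))
    N, K = X.n_neurons, f.K
    num_tests = N * K
    part = np.zeros((N, K), dtype=bool)
    results = [[None] * K for _ in range(N)]
    for n in range(N):
        trace = X.values[n]
        if not np.any(trace):
            continue  # silent neuron participates in nothing
        for k in range(K):
            res = circshift_xcorr_test(trace, f.H[k], L, p=p, num_tests=num_tests)
            part[n, k] = res.any_significant
            results[n][k] = res
    if return_results:
        return part, results
    return part


def participation_fraction(part: np.ndarray) -> float:
    """Fraction of neurons participating in at least one sequence."""
    return float(part.any(axis=1).mean())


# ---------------------------------------------------------------------------
# Application 2: song locking
# ---------------------------------------------------------------------------

def upsample_to_ms(h: np.ndarray, frame_rate_hz: float, T_ms: int) -> np.ndarray:
    """Zero-order-hold upsampling of a frame-rate series to 1 ms bins
    (preserves non-negativity and the timing of activity mass)."""
    idx = np.minimum(
        (np.arange(T_ms) * frame_rate_hz / 1000.0).astype(int), h.size - 1
    )
    return h[idx]


def song_locking(
    f: Factorization,
    song: SongFeatureMatrix,
    L_seconds: float = 1.0,
    p: float = 0.05,
) -> np.ndarray:
    """Per-factor song locking, in seconds.

    Each H row is upsampled to 1 ms resolution and tested against each of
    the 8 acoustic features with L = 1 s and Bonferroni family (2000
    timebins) x (8 features) x (K sequences). The locking of a factor is the
    total duration of significant lags, summed over features.
    """
    K = f.K
    T_ms = song.features.shape[1]
    expected_ms = int(round(f.T / f.frame_rate_hz * 1000))
    if abs(T_ms - expected_ms) > 1000:
        raise ValueError(
            f"song duration {T_ms} ms does not match neural data "
            f"({expected_ms} ms)"
        )
    T_ms = min(T_ms, expected_ms)
    L = int(round(L_seconds * 1000))
    num_tests = 8 * K
    locking = np.zeros(K)
    for k in range(K):
        h_ms = upsample_to_ms(f.H[k], f.frame_rate_hz, T_ms)
        for c in range(8):
            res = circshift_xcorr_test(
                h_ms, song.features[c, :T_ms], L, p=p, num_tests=num_tests
            )
            locking[k] += res.n_significant * 0.001
    return locking


# ---------------------------------------------------------------------------
# Application 3: factor autocorrelation
# ---------------------------------------------------------------------------

def factor_autocorrelation(
    f: Factorization,
    L_seconds: float = 1.0,
    p: float = 0.05,
) -> np.ndarray:
    """Per-factor autocorrelation summary, in seconds.

    Tests each H row against itself and integrates the duration of
    significant lags, excluding |l| smaller than one exemplar width (where
    self-overlap is trivially significant). High values indicate
    rhythmic/repeatable production of the sequence.
    """
    K = f.K
    L = int(round(L_seconds * f.frame_rate_hz))
    exclude = f.Lbins
    out = np.zeros(K)
    for k in range(K):
        h = f.H[k]
        if not np.any(h):
            continue
        res = circshift_xcorr_test(h, h, L, p=p, num_tests=K)
        keep = np.abs(res.lags) >= exclude
        out[k] = float(np.sum(res.sig_mask & keep)) / f.frame_rate_hz
    return out
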