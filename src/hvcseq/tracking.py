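"""Track a sequence factor from one data subset into another and quantify
its persistence against two null models.

With neuron identities matched across days (resolved upstream), an exemplar
W learned on one subset (e.g. pre-tutoring) is projected onto another day's
data: after mean-subtracting both along time, ``H2_tilde = W^T (*) X2``
estimates when the sequence occurs in the target data, and
``W2_tilde = X2 (*) H2_tilde^T`` re-estimates the exemplar there. Sequence
persistence is the correlation between the two exemplars, tested against a
time-shuffled null (circularly shifting each neuron's lag profile, which
destroys sequential order but keeps per-neuron activity mass) and a
neuron-shuffled null (permuting neuron rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Factorization, SongFeatureMatrix, TraceMatrix
from .convnmf import trans_conv
from .metrics import circshift_rows
from .xcorr import song_locking


@dataclass
class TrackingResult:
    H2_tilde: np.ndarray
    W2_tilde: np.ndarray
    participation_sig: np.ndarray  # boolean per neuron
    n_shuffles: int
    seed: int


def _as_tensor(W: np.ndarray) -> np.ndarray:
    """Accept a single-factor (N x L) exemplar or an (N x K x L) tensor."""
    W = np.asarray(W, dtype=float)
    if W.ndim == 2:
        return W[:, None, :]
    if W.ndim == 3:
        return W
    raise ValueError("W must be (N x L) or (N x K x L)")


def project_sequence(W: np.ndarray, X2: TraceMatrix | np.ndarray) -> np.ndarray:
    """Project exemplar(s) onto target data: mean-subtract W and X2 along
    the time dimension, then compute ``H2_tilde = W^T (*) X2``. Peaks mark
    candidate occurrences of the tracked sequence in the target data."""
    Wt = _as_tensor(W)
    X2v = X2.values if isinstance(X2, TraceMatrix) else np.asarray(X2, dtype=float)
    if Wt.shape[0] != X2v.shape[0]:
        raise ValueError(
            f"neuron mismatch: W has {Wt.shape[0]} rows, X2 has {X2v.shape[0]}"
        )
    Wc = Wt - Wt.mean(axis=2, keepdims=True)
    Xc = X2v - X2v.mean(axis=1, keepdims=True)
    H2 = trans_conv(Wc, Xc)
    return H2 if np.asarray(W).ndim == 3 else H2[0]


def _exemplar_estimate(
    Xc: np.ndarray, H2: np.ndarray, L: int, normalize: bool = False
) -> np.ndarray:
    """``W2_tilde[n, k, l] = sum_t Xc[n, t + l] * H2[k, t]``.

    With ``normalize=True`` each factor slab is divided by the norm of its
    projected timecourse, making values comparable between real and
    shuffled-control projections (whose overall scale differs)."""
    N, T = Xc.shape
    K = H2.shape[0]
    W2 = np.zeros((N, K, L))
    for lag in range(L):
        W2[:, :, lag] = Xc[:, lag:] @ H2[:, : T - lag].T
    if normalize:
        norms = np.sqrt(np.sum(H2**2, axis=1))
        norms[norms == 0] = 1.0
        W2 /= norms[None, :, None]
    return W2


def tracked_participation(
    W: np.ndarray,
    X2: TraceMatrix,
    n_shuffles: int = 100,
    p: float = 0.05,
    seed: int = 0,
) -> TrackingResult:
    """Which neurons significantly participate in the tracked sequence on
    the target day.

    The re-estimated exemplar ``W2_tilde = X2 H2_tilde^T`` is compared to
    the same quantity computed on control datasets in which each neuron's
    data is circularly shifted by a different random amount; a neuron is
    significant when any of its lag entries exceeds the null at level p,
    Bonferroni corrected for (number of neurons) x (number of time-lags).
    """
    Wt = _as_tensor(W)
    N, K, L = Wt.shape
    Wc = Wt - Wt.mean(axis=2, keepdims=True)
    Xc = X2.values - X2.values.mean(axis=1, keepdims=True)
    H2 = trans_conv(Wc, Xc)
    W2 = _exemplar_estimate(Xc, H2, L, normalize=True)

    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, N, K, L))
    for i in range(n_shuffles):
        Xs = circshift_rows(X2.values, rng)
        Xsc = Xs - Xs.mean(axis=1, keepdims=True)
        H2s = trans_conv(Wc, Xsc)
        null[i] = _exemplar_estimate(Xsc, H2s, L, normalize=True)
    q = min(100.0, 100.0 * (1.0 - p / (N * L)))
    sig = np.zeros(N, dtype=bool)
    for n in range(N):
        thr = np.percentile(null[:, n, :, :], q)
        sig[n] = bool((W2[n] > thr).any())
    return TrackingResult(
        H2_tilde=H2, W2_tilde=W2, participation_sig=sig,
        n_shuffles=n_shuffles, seed=seed,
    )


def pre_post_correlation(
    W_pre: np.ndarray,
    W_post: np.ndarray,
    n_null: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pearson correlation between two single-factor exemplars over matched
    neurons, with upper-tail p-values from two nulls.

    Time-shuffle null: each neuron's lag profile of one exemplar is
    circularly shifted by a random amount. Neuron-shuffle null: neuron rows
    of one exemplar are permuted. Returns ``(correlation, p_time,
    p_neuron)``. Near-synchronous populations weaken the neuron-shuffle
    null (permuting similar rows changes little), inflating p_neuron.
    """
    A = np.asarray(W_pre, dtype=float)
    B = np.asarray(W_post, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("exemplars must be matched (N x L) matrices")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 matched neurons")
    r = _flat_corr(A, B)
    rng = np.random.default_rng(seed)
    N, L = A.shape
    null_time = np.empty(n_null)
    null_neuron = np.empty(n_null)
    for i in range(n_null):
        Bt = np.empty_like(B)
        for n in range(N):
            Bt[n] = np.roll(B[n], int(rng.integers(0, L)))
        null_time[i] = _flat_corr(A, Bt)
        null_neuron[i] = _flat_corr(A, B[rng.permutation(N)])
    p_time = (1 + np.sum(null_time >= r)) / (n_null + 1)
    p_neuron = (1 + np.sum(null_neuron >= r)) / (n_null + 1)
    return float(r), float(p_time), float(p_neuron)


def _flat_corr(A: np.ndarray, B: np.ndarray) -> float:
    a, b = A.ravel(), B.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def locking_trajectory(
    W: np.ndarray,
    datasets_by_day: list[TraceMatrix],
    songs_by_day: list[SongFeatureMatrix],
    L_seconds: float = 1.0,
    p: float = 0.05,
) -> np.ndarray:
    """Song locking (seconds) of one tracked sequence on each day.

    The exemplar is projected onto each day's data and the resulting
    timecourse is tested against that day's 8 song features. Rising values
    across days indicate an initially latent sequence becoming locked to
    vocal output.
    """
    if len(datasets_by_day) != len(songs_by_day):
        raise ValueError("need song features for every day")
    Wt = _as_tensor(W)
    out = np.empty(len(datasets_by_day))
    for d, (tm, song) in enumerate(zip(datasets_by_day, songs_by_day)):
        if song is None:
            raise ValueError(f"missing song features for day {d}")
        H2 = project_sequence(Wt, tm)
        # Shift to non-negative support for the locking test's upsampling;
        # the test zero-means internally so the offset is irrelevant.
        f = Factorization(
            W=np.clip(Wt, 0, None), H=H2 - H2.min(axis=1, keepdims=True),
            lam=0.0, L_seconds=Wt.shape[2] / tm.frame_rate_hz, seed=0,
            frame_rate_hz=tm.frame_rate_hz,
        )
        out[d] = song_locking(f, song, L_seconds=L_seconds, p=p).sum()
    return out
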