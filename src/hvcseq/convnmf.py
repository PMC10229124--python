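"""Convolutional NMF core: fit X ~= W (*) H with a cross-factor redundancy
penalty, plus reconstruction power and the sequenciness score.

The model represents each sequence as an exemplar ``W[:, k, :]`` (neurons x
lags) convolved with a sparse occurrence timecourse ``H[k, :]``. Fitting
minimises

    ||X - W (*) H||_F^2  +  lambda * R(W, H, X)

by multiplicative updates, where ``R`` is the cross-orthogonality penalty
that charges factor pairs whose data-projected, temporally smoothed
timecourses are correlated — this is what suppresses redundant copies of the
same sequence when K is chosen larger than the true number of sequences.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import Factorization, ReconstructionStats, TraceMatrix

_EPS = 1e-10


# ---------------------------------------------------------------------------
# Elementary tensor operations
# ---------------------------------------------------------------------------

def reconstruct(W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Convolutional reconstruction X_hat = W (*) H.

    ``X_hat[n, t] = sum_k sum_l W[n, k, l] * H[k, t - l]`` with zero padding
    outside ``[0, T)``.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.ndim != 3 or H.ndim != 2 or W.shape[1] != H.shape[0]:
        raise ValueError("shape mismatch between W and H")
    N, K, L = W.shape
    T = H.shape[1]
    Xhat = np.zeros((N, T))
    for lag in range(min(L, T)):
        Xhat[:, lag:] += W[:, :, lag] @ H[:, : T - lag]
    return Xhat


def trans_conv(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Transposed convolution H_tilde = W^T (*) X.

    ``H_tilde[k, t] = sum_n sum_l W[n, k, l] * X[n, t + l]`` — the projection
    of the data onto each exemplar; peaks mark candidate occurrence times.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if W.ndim != 3 or X.ndim != 2 or W.shape[0] != X.shape[0]:
        raise ValueError("shape mismatch between W and X")
    N, K, L = W.shape
    T = X.shape[1]
    Ht = np.zeros((K, T))
    for lag in range(min(L, T)):
        Ht[:, : T - lag] += W[:, :, lag].T @ X[:, lag:]
    return Ht


def _smooth_rows(M: np.ndarray, width: int) -> np.ndarray:
    """Boxcar-smooth each row with an un-normalised window of ``width`` bins."""
    if width <= 1:
        return M.copy()
    kernel = np.ones(width)
    out = np.empty_like(M, dtype=float)
    for i in range(M.shape[0]):
        out[i] = np.convolve(M[i], kernel, mode="same")
    return out


def _penalty_value(W: np.ndarray, H: np.ndarray, X: np.ndarray) -> float:
    """Cross-orthogonality redundancy cost (lambda excluded).

    ``R = sum_{k != k'} [(W^T (*) X) S H^T]_{k k'}`` with S a boxcar of width
    ``2L - 1``.
    """
    K, L = W.shape[1], W.shape[2]
    WTX = trans_conv(W, X)
    WTXS = _smooth_rows(WTX, 2 * L - 1)
    M = WTXS @ H.T
    return float(M.sum() - np.trace(M))


def segment_mask(segment_bounds: list[tuple[int, int]], T: int, L: int) -> np.ndarray:
    """Boolean mask over timebins where H may place occurrences.

    Occurrences within ``L`` bins of a segment end would convolve across the
    file boundary into the next (independent) recording, so they are
    disallowed.
    """
    mask = np.zeros(T, dtype=bool)
    for s, e in segment_bounds:
        mask[s : max(s, e - L + 1)] = True
    return mask


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _total_cost(X, W, H, lam, Xhat=None):
    if Xhat is None:
        Xhat = reconstruct(W, H)
    cost = float(np.sum((X - Xhat) ** 2))
    if lam > 0:
        cost += lam * _penalty_value(W, H, X)
    return cost


def fit(
    X: TraceMatrix | np.ndarray,
    K: int,
    L_seconds: float,
    lam: float = 0.0,
    seed: int = 0,
    n_iter: int = 100,
    tol: float = 1e-6,
    frame_rate_hz: float | None = None,
    W0: np.ndarray | None = None,
    H0: np.ndarray | None = None,
) -> Factorization:
    """Fit a convolutional NMF by multiplicative updates.

    Parameters
    ----------
    X
        Non-negative neurons x timebins matrix (or :class:`TraceMatrix`;
        segment boundaries then mask H so occurrences cannot straddle
        independent recording files).
    K
        Number of factors requested.
    L_seconds
        Exemplar duration in seconds (converted to bins by the frame rate).
    lam
        Weight of the redundancy penalty.
    seed
        Seed of the random non-negative initialisation.
    n_iter
        Maximum multiplicative-update iterations; fitting stops early when
        the relative cost change drops below ``tol``, or when an update no
        longer decreases the cost (backtracking keeps the recorded cost
        history non-increasing).
    """
    if isinstance(X, TraceMatrix):
        tm = X
        Xv = tm.values
        fr = tm.frame_rate_hz
        bounds = tm.segment_bounds
    else:
        Xv = np.asarray(X, dtype=float)
        fr = frame_rate_hz if frame_rate_hz is not None else 30.0
        bounds = [(0, Xv.shape[1])]
    if not np.all(np.isfinite(Xv)):
        raise ValueError("input contains non-finite values")
    if np.any(Xv < 0):
        raise ValueError("input must be non-negative")
    N, T = Xv.shape
    L = max(1, int(round(L_seconds * fr)))
    if K < 1:
        raise ValueError("K must be >= 1")
    if L > T:
        raise ValueError(f"exemplar length {L} bins exceeds data extent {T}")

    rng = np.random.default_rng(seed)
    scale = Xv.max() if Xv.max() > 0 else 1.0
    W = (scale * rng.random((N, K, L)) / np.sqrt(L)
         if W0 is None else np.array(W0, dtype=float))
    H = (scale * rng.random((K, T)) / np.sqrt(K * L)
         if H0 is None else np.array(H0, dtype=float))
    hmask = segment_mask(bounds, T, L)
    H[:, ~hmask] = 0.0

    off = 1.0 - np.eye(K)
    smooth_width = 2 * L - 1
    costs = []
    Xhat = reconstruct(W, H)
    cost = _total_cost(Xv, W, H, lam, Xhat)
    costs.append(cost)
    stall = 0

    for _ in range(n_iter):
        W_prev, H_prev = W.copy(), H.copy()

        # --- H update ---------------------------------------------------
        WTX = trans_conv(W, Xv)
        WTXhat = trans_conv(W, Xhat)
        denom = WTXhat
        if lam > 0:
            WTXS = _smooth_rows(WTX, smooth_width)
            denom = denom + lam * (off @ WTXS)
        H = H * WTX / (denom + _EPS)
        H[:, ~hmask] = 0.0

        # --- W update ---------------------------------------------------
        Xhat = reconstruct(W, H)
        if lam > 0:
            SH = _smooth_rows(H, smooth_width)
            offSH = off @ SH
        Wn = np.empty_like(W)
        for lag in range(L):
            Hl = H[:, : T - lag] if lag else H
            Xl = Xv[:, lag:]
            num = Xl @ Hl.T
            den = Xhat[:, lag:] @ Hl.T
            if lam > 0:
                den = den + lam * (Xl @ offSH[:, : T - lag].T)
            Wn[:, :, lag] = W[:, :, lag] * num / (den + _EPS)
        W = Wn

        Xhat = reconstruct(W, H)
        new_cost = _total_cost(Xv, W, H, lam, Xhat)

        # Backtrack if the heuristic update increased the penalised cost:
        # interpolate geometrically toward the previous iterate, and stop
        # if no interpolated point improves (treated as converged).
        if new_cost > cost:
            improved = False
            for _bt in range(3):
                W = 0.5 * (W + W_prev)
                H = 0.5 * (H + H_prev)
                Xhat = reconstruct(W, H)
                new_cost = _total_cost(Xv, W, H, lam, Xhat)
                if new_cost <= cost:
                    improved = True
                    break
            if not improved:
                W, H = W_prev, H_prev
                break

        costs.append(new_cost)
        rel = abs(cost - new_cost) / (abs(cost) + _EPS)
        cost = new_cost
        # Multiplicative updates can stall on saddle plateaus for a few
        # iterations before escaping; require sustained convergence.
        if rel < tol:
            stall += 1
            if stall >= 5:
                break
        else:
            stall = 0

    return Factorization(
        W=W,
        H=H,
        lam=lam,
        L_seconds=L_seconds,
        seed=seed,
        frame_rate_hz=fr,
        cost_history=np.asarray(costs),
    )


# ---------------------------------------------------------------------------
# Reconstruction statistics
# ---------------------------------------------------------------------------

def power_explained(X: TraceMatrix | np.ndarray, f: Factorization) -> float:
    """Fraction of data power captured: ``1 - ||X - X_hat||^2 / ||X||^2``.

    Floored at 0. An all-zero X has undefined power; reported as 0 with a
    warning.
    """
    Xv = X.values if isinstance(X, TraceMatrix) else np.asarray(X, dtype=float)
    total = float(np.sum(Xv**2))
    if total == 0:
        warnings.warn("power_explained undefined for all-zero data; reporting 0")
        return 0.0
    Xhat = reconstruct(f.W, f.H)
    return max(0.0, 1.0 - float(np.sum((Xv - Xhat) ** 2)) / total)


def per_factor_power(X: TraceMatrix | np.ndarray, f: Factorization) -> np.ndarray:
    """Power explained by each factor alone."""
    Xv = X.values if isinstance(X, TraceMatrix) else np.asarray(X, dtype=float)
    total = float(np.sum(Xv**2))
    out = np.zeros(f.K)
    if total == 0:
        return out
    for k in range(f.K):
        Xk = reconstruct(f.W[:, [k], :], f.H[[k], :])
        out[k] = max(0.0, 1.0 - float(np.sum((Xv - Xk) ** 2)) / total)
    return out


def shuffle_timebins(
    X: TraceMatrix, rng: np.random.Generator
) -> TraceMatrix:
    """Permute timebins (columns) independently within each segment."""
    Xs = X.values.copy()
    for s, e in X.segment_bounds:
        perm = rng.permutation(e - s)
        Xs[:, s:e] = Xs[:, s + perm]
    return TraceMatrix(Xs, X.frame_rate_hz, list(X.segment_bounds), list(X.neuron_ids))


def sequenciness(
    X: TraceMatrix,
    K: int,
    L_seconds: float,
    lam: float = 0.0,
    seed: int = 0,
    n_shuffles: int = 10,
    n_iter: int = 100,
    mode: str = "refit",
) -> float:
    """Sequenciness score in [0, 1].

    ``1 - mean(power explained on timebin-shuffled X) / (power explained on
    X)``, clipped to [0, 1]. A score of 0 means all explanatory power
    survives destroying across-time structure (purely synchronous activity);
    1 means none of it does (purely temporally extended sequences).

    ``mode='refit'`` refits the factorization on each shuffled dataset from
    the same seed (default); ``mode='project'`` keeps W fixed and only
    refits H on the shuffled data.
    """
    f = fit(X, K, L_seconds, lam=lam, seed=seed, n_iter=n_iter)
    p0 = power_explained(X, f)
    if p0 <= 0:
        raise ValueError("zero power explained on original data; score undefined")
    rng = np.random.default_rng(seed)
    powers = []
    for _ in range(n_shuffles):
        Xs = shuffle_timebins(X, rng)
        if mode == "refit":
            fs = fit(Xs, K, L_seconds, lam=lam, seed=seed, n_iter=n_iter)
        elif mode == "project":
            fs = _refit_h_only(Xs, f, n_iter=n_iter)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        powers.append(power_explained(Xs, fs))
    score = 1.0 - float(np.mean(powers)) / p0
    return float(np.clip(score, 0.0, 1.0))


def _refit_h_only(X: TraceMatrix, f: Factorization, n_iter: int = 100) -> Factorization:
    """Refit H with W held fixed (multiplicative updates on H alone)."""
    Xv = X.values
    T = Xv.shape[1]
    rng = np.random.default_rng(f.seed)
    scale = Xv.max() if Xv.max() > 0 else 1.0
    H = scale * rng.random((f.K, T)) / np.sqrt(f.K * f.Lbins)
    hmask = segment_mask(X.segment_bounds, T, f.Lbins)
    H[:, ~hmask] = 0.0
    for _ in range(n_iter):
        Xhat = reconstruct(f.W, H)
        H = H * trans_conv(f.W, Xv) / (trans_conv(f.W, Xhat) + _EPS)
        H[:, ~hmask] = 0.0
    return Factorization(
        W=f.W, H=H, lam=f.lam, L_seconds=f.L_seconds, seed=f.seed,
        frame_rate_hz=f.frame_rate_hz,
    )


def reconstruction_stats(
    X: TraceMatrix,
    f: Factorization,
    seq_score: float | None = None,
) -> ReconstructionStats:
    return ReconstructionStats(
        power_explained=power_explained(X, f),
        sequenciness=float("nan") if seq_score is None else seq_score,
        per_factor_power=per_factor_power(X, f),
    )
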