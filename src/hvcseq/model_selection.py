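"""Model selection: choose the redundancy-penalty weight, estimate the
number of significant sequences, and select a consistent factorization.

Protocol: sweep lambda at K = 10 and L = 0.5 s to find the crossover
lambda0 where the (normalized) redundancy cost falls below the reconstruction
cost; count significant factors — fit on 75% of segments, score each
factor's held-out projection skewness against circularly lag-shifted
exemplar nulls with Bonferroni correction — at lambda0 and 2*lambda0 across
several seeds; take the midpoint of the two modal counts as the estimate;
then refit 25 times at that K and keep the run most consistent with the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import skew

from .containers import Factorization, TraceMatrix
from .convnmf import _penalty_value, _smooth_rows, fit, reconstruct, trans_conv


@dataclass
class LambdaSweep:
    lambdas: np.ndarray
    recon_cost: np.ndarray
    xcorr_cost: np.ndarray  # redundancy (cross-correlation) cost
    lambda0: float


@dataclass
class SignificanceReport:
    per_factor_pvalue: np.ndarray
    n_significant: int
    train_frac: float
    alpha: float


@dataclass
class ConsistencyMatrix:
    similarity: np.ndarray  # runs x runs, symmetric, diagonal 1
    chosen_run: int


def sweep_lambda(
    X: TraceMatrix,
    K: int = 10,
    L_seconds: float = 0.5,
    grid: np.ndarray | None = None,
    seed: int = 0,
    n_iter: int = 60,
) -> LambdaSweep:
    """Sweep the penalty weight and locate the crossover lambda0.

    Each lambda is fit from the same seed; reconstruction cost rises and
    redundancy cost falls with lambda. Both curves are min-max normalized
    over the sweep and lambda0 is the first grid point where normalized
    redundancy <= normalized reconstruction. If the curves never cross, the
    grid maximum is returned with a warning.
    """
    if grid is None:
        grid = np.logspace(-4, 0, 9)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("lambda grid must contain at least 2 points")
    if grid.max() / max(grid.min(), 1e-300) < 100:
        raise ValueError("lambda grid must span at least 2 decades")
    recon = np.empty(grid.size)
    red = np.empty(grid.size)
    for i, lam in enumerate(grid):
        f = fit(X, K, L_seconds, lam=lam, seed=seed, n_iter=n_iter)
        Xhat = reconstruct(f.W, f.H)
        recon[i] = float(np.sum((X.values - Xhat) ** 2))
        red[i] = _penalty_value(f.W, f.H, X.values)

    def _norm(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    rn, dn = _norm(recon), _norm(red)
    cross = np.flatnonzero(dn <= rn)
    if cross.size:
        i = int(cross[0])
        if i == 0:
            lambda0 = float(grid[0])
        else:
            # Interpolate the exact crossover of the normalized curves in
            # log-lambda between the bracketing grid points.
            d0 = dn[i - 1] - rn[i - 1]
            d1 = dn[i] - rn[i]
            frac = d0 / (d0 - d1) if d0 != d1 else 1.0
            lambda0 = float(
                10 ** (np.log10(grid[i - 1])
                       + frac * (np.log10(grid[i]) - np.log10(grid[i - 1])))
            )
    else:
        warnings.warn("cost curves never cross; lambda0 set to grid maximum")
        lambda0 = float(grid[-1])
    return LambdaSweep(lambdas=grid, recon_cost=recon, xcorr_cost=red,
                       lambda0=lambda0)


def split_segments(
    n_segments: int, train_frac: float, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Seeded random split of whole segments into train/test."""
    order = rng.permutation(n_segments)
    n_train = int(round(train_frac * n_segments))
    n_train = min(max(n_train, 1), n_segments - 1)
    return sorted(order[:n_train].tolist()), sorted(order[n_train:].tolist())


def _shift_w_rows(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Null exemplar: circularly shift each neuron's lag profile by a random
    amount (the same shift across factors for a given neuron)."""
    L = W.shape[2]
    out = np.empty_like(W)
    for n in range(W.shape[0]):
        out[n] = np.roll(W[n], int(rng.integers(0, L)), axis=-1)
    return out


def count_significant(
    X: TraceMatrix,
    K: int = 10,
    L_seconds: float = 0.5,
    lam: float = 0.0,
    seed: int = 0,
    train_frac: float = 0.75,
    alpha: float = 0.05,
    n_nulls: int = 500,
    n_iter: int = 60,
) -> SignificanceReport:
    """Count factors whose sequences generalize to held-out data.

    Factors are fit on the training segments (75% by default); each factor
    is scored by the skewness of its projection ``W^T (*) X_test`` onto the
    test segments (a sequence that recurs in held-out data produces a
    sparse, strongly right-skewed projection). Null skewness comes from
    exemplars whose per-neuron lag profiles are circularly shifted by random
    amounts; p is the upper-tail rank and factors are counted at the
    Bonferroni level alpha / K.
    """
    n_seg = len(X.segment_bounds)
    if n_seg < 2:
        raise ValueError("need at least 2 segments to split train/test")
    if 1.0 / (n_nulls + 1) >= alpha / K:
        warnings.warn(
            f"n_nulls={n_nulls} cannot resolve p < alpha/K = {alpha / K:.4g}; "
            "no factor can reach significance — increase n_nulls"
        )
    rng = np.random.default_rng(seed)
    train_idx, test_idx = split_segments(n_seg, train_frac, rng)
    X_train = X.subset_segments(train_idx)
    X_test = X.subset_segments(test_idx)
    L = int(round(L_seconds * X.frame_rate_hz))
    if X_test.n_timebins < 2 * L:
        raise ValueError("test set shorter than 2L")

    f = fit(X_train, K, L_seconds, lam=lam, seed=seed, n_iter=n_iter)
    # Factors that never occur in the training data (empty timecourse, e.g.
    # suppressed by the penalty) have no sequence to test: p = 1.
    h_load = f.H.sum(axis=1)
    active = h_load > 1e-12 * max(h_load.max(), 1e-300)
    stats = _projection_skewness(f.W, X_test.values)
    null = np.empty((n_nulls, K))
    for i in range(n_nulls):
        Wn = _shift_w_rows(f.W, rng)
        null[i] = _projection_skewness(Wn, X_test.values)
    # Upper-tail rank p-value per factor against its own null distribution.
    pvals = np.ones(K)
    for k in range(K):
        if not active[k] or np.isnan(stats[k]):
            continue
        pvals[k] = (1 + np.sum(null[:, k] >= stats[k])) / (n_nulls + 1)
    n_sig = int(np.sum(pvals < alpha / K))
    return SignificanceReport(
        per_factor_pvalue=pvals, n_significant=n_sig,
        train_frac=train_frac, alpha=alpha,
    )


def _projection_skewness(W: np.ndarray, Xv: np.ndarray) -> np.ndarray:
    Ht = trans_conv(W, Xv)
    out = np.full(W.shape[1], np.nan)
    for k in range(W.shape[1]):
        row = Ht[k]
        if np.ptp(row) > 0:
            out[k] = skew(row)
    return out


def _mode(values: np.ndarray) -> int:
    counts = np.bincount(np.asarray(values, dtype=int))
    return int(np.argmax(counts))  # ties broken toward the smaller count


def _midpoint_round_down(a: int, b: int) -> int:
    """Midpoint of two modal counts, rounded half-down (modes 2 and 3 -> 2)."""
    return int(np.ceil((a + b) / 2.0 - 0.5))


def estimate_k(
    X: TraceMatrix,
    L_seconds: float,
    lambda0: float,
    n_runs: int = 5,
    K: int = 10,
    seed: int = 0,
    n_nulls: int = 500,
    n_iter: int = 60,
    train_frac: float = 0.75,
    alpha: float = 0.05,
) -> int:
    """Estimate the number of sequences: the midpoint (rounded half-down) of
    the modal significant-factor counts at lambda0 and at 2*lambda0 across
    ``n_runs`` seeded train/test splits."""
    counts = {}
    for lam in (lambda0, 2 * lambda0):
        c = []
        for r in range(n_runs):
            rep = count_significant(
                X, K=K, L_seconds=L_seconds, lam=lam,
                seed=seed + 1000 * r, train_frac=train_frac,
                alpha=alpha, n_nulls=n_nulls, n_iter=n_iter,
            )
            c.append(rep.n_significant)
        counts[lam] = np.asarray(c)
    m1 = _mode(counts[lambda0])
    m2 = _mode(counts[2 * lambda0])
    return _midpoint_round_down(m1, m2)


def factorization_similarity(
    f1: Factorization, f2: Factorization
) -> float:
    """Consistency of two factorizations, in [0, 1].

    Greedily matches factor pairs by the correlation of their box-smoothed
    (width 2L - 1) H timecourses and averages the matched correlations
    (negative values clipped to 0; zero-variance timecourses contribute 0).
    """
    K = f1.K
    width = 2 * f1.Lbins - 1
    H1 = _smooth_rows(f1.H, width)
    H2 = _smooth_rows(f2.H, width)
    C = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            C[i, j] = _safe_corr(H1[i], H2[j])
    sims = []
    C = C.copy()
    for _ in range(K):
        i, j = np.unravel_index(np.argmax(C), C.shape)
        sims.append(max(0.0, C[i, j]))
        C[i, :] = -np.inf
        C[:, j] = -np.inf
    return float(np.mean(sims))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_consistent(
    X: TraceMatrix,
    K: int,
    L_seconds: float,
    n_runs: int = 25,
    lam: float = 0.0,
    seed: int = 0,
    n_iter: int = 100,
    seeds: list[int] | None = None,
) -> tuple[Factorization, ConsistencyMatrix]:
    """Fit ``n_runs`` random restarts and keep the run whose factorization
    is most consistent with the others (maximal median pairwise
    similarity). Restart seeds derive from ``seed`` unless ``seeds`` is
    given explicitly."""
    if seeds is None:
        seeds = [seed + 7919 * r for r in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("seeds must have length n_runs")
    runs = [
        fit(X, K, L_seconds, lam=lam, seed=s, n_iter=n_iter) for s in seeds
    ]
    S = np.eye(n_runs)
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            s = factorization_similarity(runs[i], runs[j])
            S[i, j] = S[j, i] = s
    if n_runs == 1:
        chosen = 0
    else:
        med = np.array([
            np.median(np.delete(S[i], i)) for i in range(n_runs)
        ])
        chosen = int(np.argmax(med))
    return runs[chosen], ConsistencyMatrix(similarity=S, chosen_run=chosen)
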