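"""Factorization core: reconstruction oracle, fitting, power, sequenciness."""

import numpy as np
import pytest

import hvcseq
from hvcseq import convnmf
from hvcseq.containers import Factorization, TraceMatrix
from hvcseq.convnmf import (
    fit,
    power_explained,
    reconstruct,
    sequenciness,
    trans_conv,
)
from hvcseq.validate import occurrence_time_correlation


def brute_reconstruct(W, H):
    """Triple-loop convolutional reconstruction oracle."""
    N, K, L = W.shape
    T = H.shape[1]
    X = np.zeros((N, T))
    for n in range(N):
        for k in range(K):
            for lag in range(L):
                for t in range(T):
                    if 0 <= t - lag < T:
                        X[n, t] += W[n, k, lag] * H[k, t - lag]
    return X


def brute_trans_conv(W, X):
    """Triple-loop transposed-convolution oracle."""
    N, K, L = W.shape
    T = X.shape[1]
    H = np.zeros((K, T))
    for k in range(K):
        for t in range(T):
            for lag in range(L):
                if t + lag < T:
                    for n in range(N):
                        H[k, t] += W[n, k, lag] * X[n, t + lag]
    return H


@pytest.mark.parametrize("seed", range(5))
def test_reconstruct_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    N, K, L, T = rng.integers(1, 11, size=4)
    W = rng.random((N, K, L))
    H = rng.random((K, T))
    np.testing.assert_allclose(
        reconstruct(W, H), brute_reconstruct(W, H), atol=1e-12
    )


@pytest.mark.parametrize("seed", range(5))
def test_trans_conv_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    N, K, L, T = rng.integers(1, 11, size=4)
    W = rng.random((N, K, L))
    X = rng.random((N, T))
    np.testing.assert_allclose(
        trans_conv(W, X), brute_trans_conv(W, X), atol=1e-12
    )


def test_reconstruct_unit_impulse():
    W = np.zeros((2, 1, 3))
    W[0, 0, 0] = 1.0
    H = np.zeros((1, 10))
    H[0, 5] = 1.0
    X = reconstruct(W, H)
    expected = np.zeros((2, 10))
    expected[0, 5] = 1.0
    np.testing.assert_array_equal(X, expected)


def test_reconstruct_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shape mismatch"):
        reconstruct(np.ones((2, 3, 4)), np.ones((2, 10)))


def test_ground_truth_factorization_reconstructs_spikes(pure_sequences_raw):
    """The planted W and occurrence timecourses reproduce the noise-free
    spike raster exactly (occurrences do not overlap)."""
    from conftest import ground_truth_factorization

    tm, _, gt = pure_sequences_raw
    f = ground_truth_factorization(gt, tm.n_timebins)
    np.testing.assert_allclose(reconstruct(f.W, f.H), gt.spikes, atol=1e-12)
    assert power_explained(gt.spikes, f) >= 0.999


def test_power_explained_extremes():
    rng = np.random.default_rng(0)
    X = rng.random((4, 30))
    perfect = Factorization(
        W=np.zeros((4, 1, 1)), H=np.zeros((1, 30)), lam=0.0,
        L_seconds=1 / 30, seed=0, frame_rate_hz=30.0,
    )
    assert power_explained(X, perfect) == 0.0  # W = 0 explains nothing
    with pytest.warns(UserWarning, match="all-zero"):
        assert power_explained(np.zeros((4, 30)), perfect) == 0.0


def test_fit_recovers_planted_factors(pure_sequences_deconv):
    deconv, _, gt = pure_sequences_deconv
    f = fit(deconv, K=2, L_seconds=0.5, lam=0.0, seed=0, n_iter=100)
    corr = occurrence_time_correlation(f, gt)
    assert np.all(corr > 0.8)
    assert power_explained(deconv, f) > 0.8


def test_cost_history_non_increasing_small_instances():
    rng = np.random.default_rng(7)
    for trial in range(5):
        X = rng.random((15, 200)) * (rng.random((15, 200)) < 0.1)
        tm = TraceMatrix(X, 30.0, [(0, 100), (100, 200)])
        for lam in (0.0, 0.01):
            f = fit(tm, K=3, L_seconds=5 / 30, lam=lam, seed=trial, n_iter=40)
            d = np.diff(f.cost_history)
            rel = d / np.abs(f.cost_history[:-1])
            assert np.all(rel <= 1e-7)


def test_zero_matrix_fit_degenerates_gracefully():
    tm = TraceMatrix(np.zeros((5, 120)), 30.0, [(0, 120)])
    f = fit(tm, K=2, L_seconds=5 / 30, seed=0, n_iter=20)
    assert np.allclose(reconstruct(f.W, f.H), 0, atol=1e-8)
    with pytest.warns(UserWarning):
        assert power_explained(tm, f) == 0.0


def test_fit_rejects_bad_inputs():
    tm = TraceMatrix(np.ones((3, 50)), 30.0, [(0, 50)])
    with pytest.raises(ValueError, match="exemplar length"):
        fit(tm, K=1, L_seconds=10.0)
    bad = np.ones((3, 50))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit(bad, K=1, L_seconds=0.1)
    with pytest.raises(ValueError, match="non-negative"):
        fit(-np.ones((3, 50)), K=1, L_seconds=0.1)


def test_neuron_permutation_equivariance():
    """Permuting neuron rows of X (and of the initialization) permutes W
    rows identically and leaves H and the explained power unchanged."""
    rng = np.random.default_rng(4)
    N, K, L, T = 12, 2, 4, 150
    X = rng.random((N, T)) * (rng.random((N, T)) < 0.2)
    W0 = rng.random((N, K, L))
    H0 = rng.random((K, T))
    perm = rng.permutation(N)
    f1 = fit(X, K, L / 30, seed=0, n_iter=30, W0=W0, H0=H0)
    f2 = fit(X[perm], K, L / 30, seed=0, n_iter=30, W0=W0[perm], H0=H0)
    np.testing.assert_allclose(f1.W[perm], f2.W, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(f1.H, f2.H, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(f1.cost_history, f2.cost_history, rtol=1e-10)


def test_segment_mask_blocks_cross_file_occurrences():
    tm = TraceMatrix(np.random.default_rng(1).random((4, 200)), 30.0,
                     [(0, 100), (100, 200)])
    f = fit(tm, K=1, L_seconds=10 / 30, seed=0, n_iter=10)
    L = f.Lbins
    assert np.all(f.H[:, 100 - L + 1 : 100] == 0)
    assert np.all(f.H[:, 200 - L + 1 :] == 0)


def test_sequenciness_modes_and_errors(pure_sequences_deconv):
    deconv, _, _ = pure_sequences_deconv
    s = sequenciness(deconv, K=2, L_seconds=0.5, seed=0, n_shuffles=2,
                     n_iter=40, mode="project")
    assert 0.0 <= s <= 1.0
    with pytest.raises(ValueError, match="unknown mode"):
        sequenciness(deconv, K=2, L_seconds=0.5, n_shuffles=1, mode="bogus")
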