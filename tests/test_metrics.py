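"""Occurrence detection, coverage, reliability, specificity, abnormalities."""

import numpy as np
import pytest

import hvcseq
from conftest import ground_truth_factorization
from hvcseq import metrics, preprocess
from hvcseq.containers import TraceMatrix
from hvcseq.metrics import Occurrence, OccurrenceSet


def make_occurrence_set(occs, K, T, L):
    covered = np.zeros((K, T), dtype=bool)
    for o in occs:
        covered[o.factor, o.onset : min(T, o.onset + o.duration + L)] = True
    return OccurrenceSet(occurrences=occs, covered_mask=covered,
                         thresholds=np.zeros(K), Lbins=L)


def test_projection_on_toy_matches_brute_force():
    """H_tilde = W^T (*) X on a 5 x 30 toy equals the explicit triple sum."""
    rng = np.random.default_rng(0)
    W = rng.random((5, 2, 4))
    X = rng.random((5, 30))
    from hvcseq.convnmf import trans_conv

    expected = np.zeros((2, 30))
    for k in range(2):
        for t in range(30):
            for lag in range(4):
                if t + lag < 30:
                    expected[k, t] += W[:, k, lag] @ X[:, t + lag]
    np.testing.assert_allclose(trans_conv(W, X), expected, atol=1e-12)


def test_detection_recovers_planted_occurrences(pure_sequences_deconv):
    deconv, _, gt = pure_sequences_deconv
    f = ground_truth_factorization(gt, deconv.n_timebins)
    occ = metrics.detect_occurrences(deconv, f, seed=0)
    for k in range(2):
        det = occ.onsets(k)
        true = gt.occurrences[k].onsets
        recall = np.mean([np.any(np.abs(det - t) <= 2) for t in true])
        assert recall >= 0.95


def test_noise_only_occurrence_rate_at_type_one_level(noise_only_deconv):
    """Projecting foreign exemplars onto structureless data detects almost
    nothing (threshold is Bonferroni-corrected)."""
    deconv, _, _ = noise_only_deconv
    rng = np.random.default_rng(1)
    from hvcseq.containers import Factorization

    W = rng.random((deconv.n_neurons, 2, 15)) * \
        (rng.random((deconv.n_neurons, 2, 15)) < 0.1)
    f = Factorization(W=W, H=np.zeros((2, deconv.n_timebins)), lam=0.0,
                      L_seconds=0.5, seed=0, frame_rate_hz=30.0)
    occ = metrics.detect_occurrences(deconv, f, seed=1)
    # expected false bins: p/Num * K * T ~= 0.05; allow a few merges
    assert len(occ.occurrences) <= 3


def test_higher_threshold_detects_subset(pure_sequences_deconv):
    deconv, _, gt = pure_sequences_deconv
    f = ground_truth_factorization(gt, deconv.n_timebins)
    loose = metrics.detect_occurrences(deconv, f, seed=0, p=0.05)
    strict = metrics.detect_occurrences(deconv, f, seed=0, p=0.001)
    assert np.all(strict.covered_mask <= loose.covered_mask)


def test_coverage_extremes_and_monotonicity():
    T, L, K = 300, 15, 1
    bounds = [(0, 150), (150, 300)]
    tiling = [Occurrence(0, s, 15) for s in range(0, 300 - 30, 15)]
    occ_full = make_occurrence_set(tiling, K, T, L)
    _, overall = metrics.coverage(occ_full, bounds)
    assert overall >= 95.0

    occ_empty = make_occurrence_set([], K, T, L)
    per_bout, overall0 = metrics.coverage(occ_empty, bounds)
    assert overall0 == 0.0
    assert np.all(per_bout == 0.0)

    # adding an occurrence never decreases coverage
    occ_one = make_occurrence_set([Occurrence(0, 10, 5)], K, T, L)
    occ_two = make_occurrence_set(
        [Occurrence(0, 10, 5), Occurrence(0, 200, 5)], K, T, L
    )
    assert metrics.coverage(occ_two, bounds)[1] >= \
        metrics.coverage(occ_one, bounds)[1]


def test_coverage_rejects_zero_length_bout():
    occ = make_occurrence_set([], 1, 10, 2)
    with pytest.raises(ValueError, match="zero-length"):
        metrics.coverage(occ, [(5, 5)])


def test_partial_coverage_on_gappy_fixture(pure_sequences_deconv):
    deconv, _, gt = pure_sequences_deconv
    f = ground_truth_factorization(gt, deconv.n_timebins)
    occ = metrics.detect_occurrences(deconv, f, seed=0)
    _, overall = metrics.coverage(occ, deconv.segment_bounds)
    assert 0.0 < overall < 100.0


def test_reliability_full_participation_near_one(pure_sequences_deconv):
    deconv, _, gt = pure_sequences_deconv
    f = ground_truth_factorization(gt, deconv.n_timebins)
    occ = metrics.detect_occurrences(deconv, f, seed=0)
    rel = metrics.reliability(deconv, f, occ, gt.members)
    assert np.nanmean(rel) > 0.95


def test_reliability_recovers_participation_probability():
    vals = []
    for seed in range(3):
        tm, _, gt = hvcseq.make_fixture(
            "pure_sequences", seed=seed, participation_prob=0.6,
            noise_sd=0.02,
        )
        deconv, _ = preprocess.preprocess_traces(tm)
        f = ground_truth_factorization(gt, deconv.n_timebins)
        occ = metrics.detect_occurrences(deconv, f, seed=seed)
        vals.append(np.nanmean(metrics.reliability(deconv, f, occ, gt.members)))
    assert abs(np.mean(vals) - 0.6) < 0.05


def test_reliability_undefined_below_min_occurrences():
    X = np.zeros((3, 200))
    tm = TraceMatrix(X, 30.0, [(0, 200)])
    f = ground_truth_factorization_stub()
    occ = make_occurrence_set([Occurrence(0, 10, 3)], 1, 200, 15)
    rel = metrics.reliability(tm, f, occ, np.ones((3, 1), dtype=bool))
    assert np.all(np.isnan(rel))


def ground_truth_factorization_stub():
    from hvcseq.containers import Factorization

    return Factorization(W=np.ones((3, 1, 15)), H=np.zeros((1, 200)),
                         lam=0.0, L_seconds=0.5, seed=0, frame_rate_hz=30.0)


def test_specificity_hand_built_half():
    """A neuron with half its activity inside covered spans scores 0.5."""
    X = np.zeros((1, 100))
    X[0, [10, 12, 60, 70]] = 1.0
    tm = TraceMatrix(X, 30.0, [(0, 100)])
    occ = make_occurrence_set([Occurrence(0, 8, 2)], 1, 100, 5)
    # covered span: bins 8..14 -> events at 10, 12 inside; 60, 70 outside
    part = np.ones((1, 1), dtype=bool)
    spec = metrics.sequence_specificity(tm, occ, part)
    assert spec[0] == pytest.approx(0.5)


def test_specificity_without_background_near_one(pure_sequences_deconv):
    deconv, _, gt = pure_sequences_deconv
    f = ground_truth_factorization(gt, deconv.n_timebins)
    occ = metrics.detect_occurrences(deconv, f, seed=0)
    spec = metrics.sequence_specificity(deconv, occ, gt.members)
    assert np.nanmean(spec) > 0.95


def brute_persistent_scan(act, min_neurons, min_dur):
    """Sliding-window oracle: all window starts where >= min_neurons are
    active at every bin of the window."""
    N, T = act.shape
    hits = []
    for t in range(T - min_dur + 1):
        if (act[:, t : t + min_dur].all(axis=1)).sum() >= min_neurons:
            hits.append(t)
    return hits


def test_persistent_activity_trivial_cases():
    fr = 30.0
    X = np.zeros((5, 300))
    X[:3, 100:118] = 1.0  # 3 neurons, 600 ms
    rep = metrics.detect_persistent_activity(TraceMatrix(X, fr, [(0, 300)]))
    assert len(rep.persistent_episodes) == 1
    onset, offset, count = rep.persistent_episodes[0]
    assert count >= 3
    assert offset - onset >= 15

    X2 = np.zeros((5, 300))
    X2[:2, 100:130] = 1.0  # only 2 neurons: below threshold
    rep2 = metrics.detect_persistent_activity(TraceMatrix(X2, fr, [(0, 300)]))
    assert rep2.persistent_episodes == []


def test_persistent_activity_matches_brute_force_scan():
    rng = np.random.default_rng(6)
    act = rng.random((8, 400)) < 0.55
    X = act.astype(float)
    tm = TraceMatrix(X, 30.0, [(0, 400)])
    rep = metrics.detect_persistent_activity(tm, smooth_bins=1)
    from scipy.ndimage import maximum_filter1d

    sm = maximum_filter1d(act.astype(np.int8), size=1, axis=1).astype(bool)
    hits = brute_persistent_scan(sm, 3, 15)
    covered = set()
    for onset, offset, _ in rep.persistent_episodes:
        covered.update(range(onset, offset - 15 + 1))
    assert covered == set(hits)


def test_planted_episode_count_within_poisson_ci():
    """On rasters with planted episodes, the detected count matches the
    planted count."""
    total_planted = total_detected = 0
    for seed in range(4):
        tm, _, gt = hvcseq.make_fixture(
            "isolate_like", seed=seed, persistent_episode_rate=3.0,
            noise_sd=0.0, background_event_rate_hz=0.0, truncation_prob=0.0,
        )
        raster = TraceMatrix(gt.spikes, tm.frame_rate_hz,
                             list(tm.segment_bounds))
        rep = metrics.detect_persistent_activity(raster)
        total_planted += len(gt.persistent_episodes)
        total_detected += len(rep.persistent_episodes)
    assert total_planted > 0
    # detection on the clean raster recovers essentially every episode
    assert abs(total_detected - total_planted) <= \
        2 * np.sqrt(total_planted) + 2


def test_truncation_cv_flags_variable_durations():
    occs = [Occurrence(0, s, d) for s, d in
            [(10, 5), (50, 15), (100, 30), (150, 8)]] + \
           [Occurrence(1, s, 10) for s in (10, 50, 100)]
    occ = make_occurrence_set(occs, 2, 300, 15)
    cv = metrics.truncation_cv(occ, 2)
    assert cv[0] > 0.3  # variable factor
    assert cv[1] == pytest.approx(0.0)  # constant durations
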