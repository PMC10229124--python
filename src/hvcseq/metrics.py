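"""Occurrence detection, bout coverage, rendition reliability,
sequence-specific activity, and qualitative abnormality detectors
(persistent activity and variable truncation).

Occurrence times of each sequence are the moments when the data projection
``H_tilde = W^T (*) X`` exceeds what per-neuron circularly shifted data
would produce by chance; the covered span of an occurrence extends over the
exemplar duration ("the sequence is convolved with the corresponding W").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .containers import Factorization, TraceMatrix
from .convnmf import trans_conv


@dataclass
class Occurrence:
    factor: int
    onset: int  # global bin
    duration: int  # bins of supra-threshold projection


@dataclass
class OccurrenceSet:
    """Detected occurrences plus per-factor coverage masks."""

    occurrences: list[Occurrence]
    covered_mask: np.ndarray  # K x T bool; bins inside [onset, onset+dur+L)
    thresholds: np.ndarray  # per-factor detection threshold
    Lbins: int

    def by_factor(self, k: int) -> list[Occurrence]:
        return [o for o in self.occurrences if o.factor == k]

    def onsets(self, k: int) -> np.ndarray:
        return np.asarray([o.onset for o in self.by_factor(k)], dtype=int)

    @property
    def any_covered(self) -> np.ndarray:
        return self.covered_mask.any(axis=0)


@dataclass
class AbnormalityReport:
    """Persistent-activity episodes and truncation variability."""

    persistent_episodes: list[tuple[int, int, int]]  # (onset, offset, n_neurons)
    truncation_cv: np.ndarray = field(default_factory=lambda: np.empty(0))


def circshift_rows(
    X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Circularly shift each row by an independent random amount."""
    T = X.shape[1]
    out = np.empty_like(X)
    for n in range(X.shape[0]):
        out[n] = np.roll(X[n], int(rng.integers(0, T)))
    return out


def detect_occurrences(
    X: TraceMatrix,
    f: Factorization,
    n_shuffles: int = 20,
    p: float = 0.05,
    num_comparisons: int | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Detect when each sequence occurs.

    The per-factor threshold is the Bonferroni-corrected 95th percentile —
    percentile ``100 * (1 - p / Num)`` with ``Num = K * T`` by default — of
    the projection of per-neuron circularly shifted data onto the same
    exemplars. Supra-threshold runs closer than L/2 bins are merged into one
    occurrence (projection peaks are exemplar-broad).
    """
    Ht = trans_conv(f.W, X.values)
    K, T = Ht.shape
    L = f.Lbins
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, K, T))
    for i in range(n_shuffles):
        Xs = circshift_rows(X.values, rng)
        null[i] = trans_conv(f.W, Xs)
    num = num_comparisons if num_comparisons is not None else K * T
    q = min(100.0, 100.0 * (1.0 - p / max(1, num)))
    thresholds = np.array(
        [np.percentile(null[:, k, :], q) for k in range(K)]
    )

    occurrences: list[Occurrence] = []
    covered = np.zeros((K, T), dtype=bool)
    min_gap = max(1, L // 2)
    for k in range(K):
        above = Ht[k] > thresholds[k]
        runs = _find_runs(above)
        merged = _merge_runs(runs, min_gap)
        for s, e in merged:
            occurrences.append(Occurrence(factor=k, onset=s, duration=e - s))
            covered[k, s : min(T, e + L)] = True
    return OccurrenceSet(
        occurrences=occurrences, covered_mask=covered,
        thresholds=thresholds, Lbins=L,
    )


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, end) end-exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def _merge_runs(
    runs: list[tuple[int, int]], min_gap: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage(
    occ: OccurrenceSet,
    segment_bounds: list[tuple[int, int]],
) -> tuple[np.ndarray, float]:
    """Percent of each bout's timebins covered by at least one sequence,
    and the overall percentage. Adding occurrences never decreases it."""
    anyc = occ.any_covered
    per_bout = []
    for s, e in segment_bounds:
        if e <= s:
            raise ValueError("zero-length bout")
        per_bout.append(100.0 * float(anyc[s:e].mean()))
    overall = 100.0 * float(
        np.mean(np.concatenate([anyc[s:e] for s, e in segment_bounds]))
    )
    return np.asarray(per_bout), overall


def preferred_lags(
    X: TraceMatrix,
    occ: OccurrenceSet,
    participation: np.ndarray,
) -> np.ndarray:
    """Lag (bins after occurrence onset, within the exemplar) at which each
    participating neuron's activity across renditions is maximal; -1 for
    non-participants."""
    N = X.n_neurons
    K = participation.shape[1]
    T = X.n_timebins
    L = occ.Lbins
    lags = np.full((N, K), -1, dtype=int)
    for k in range(K):
        onsets = occ.onsets(k)
        if onsets.size == 0:
            continue
        for n in np.flatnonzero(participation[:, k]):
            acc = np.zeros(L)
            for o in onsets:
                seg = X.values[n, o : o + L]
                acc[: seg.size] += seg
            lags[n, k] = int(np.argmax(acc))
    return lags


def reliability(
    X: TraceMatrix,
    f: Factorization,
    occ: OccurrenceSet,
    participation: np.ndarray,
    window: int = 3,
    event_threshold: float | None = None,
    min_occurrences: int = 5,
) -> np.ndarray:
    """Fraction of its factor's occurrences at which each participating
    neuron emits an event within +-window bins of its preferred lag.

    NaN for non-participants and for factors with fewer than
    ``min_occurrences`` occurrences. ``event_threshold`` defaults to 5% of
    each neuron's maximum (deconvolved) amplitude.
    """
    N = X.n_neurons
    K = participation.shape[1]
    T = X.n_timebins
    out = np.full((N, K), np.nan)
    lags = preferred_lags(X, occ, participation)
    for k in range(K):
        onsets = occ.onsets(k)
        if onsets.size < min_occurrences:
            continue
        for n in np.flatnonzero(participation[:, k]):
            thr = event_threshold
            if thr is None:
                mx = X.values[n].max()
                thr = 0.05 * mx if mx > 0 else 0.0
            hits = 0
            for o in onsets:
                c = o + lags[n, k]
                lo, hi = max(0, c - window), min(T, c + window + 1)
                if lo < hi and X.values[n, lo:hi].max() > thr:
                    hits += 1
            out[n, k] = hits / onsets.size
    return out


def sequence_specificity(
    X: TraceMatrix,
    occ: OccurrenceSet,
    participation: np.ndarray,
) -> np.ndarray:
    """Per participating neuron: fraction of its summed deconvolved activity
    that falls inside the covered spans of its factors. NaN for silent or
    non-participating neurons."""
    N = X.n_neurons
    out = np.full(N, np.nan)
    for n in range(N):
        ks = np.flatnonzero(participation[n])
        if ks.size == 0:
            continue
        total = X.values[n].sum()
        if total == 0:
            continue
        inside = occ.covered_mask[ks].any(axis=0)
        out[n] = float(X.values[n, inside].sum() / total)
    return out


def detect_persistent_activity(
    X: TraceMatrix,
    min_neurons: int = 3,
    min_dur_s: float = 0.5,
    smooth_bins: int = 2,
) -> AbnormalityReport:
    """Find persistent-activity episodes: intervals of at least
    ``min_dur_s`` (within a segment) throughout which at least
    ``min_neurons`` of the *same* neurons stay continuously active.

    Activity is binarized as event rate > 0 after box-smoothing of width
    ``smooth_bins``. Sequences of brief, staggered bursts do not qualify:
    each participating neuron must itself remain active across the whole
    window, which is the atypical "ensemble persistent activity" mode.
    """
    # Box-smoothing followed by "> 0" is exactly binary dilation.
    act = maximum_filter1d((X.values > 0).astype(np.int8),
                           size=max(1, smooth_bins), axis=1,
                           mode="constant").astype(bool)
    min_dur = max(1, int(round(min_dur_s * X.frame_rate_hz)))
    episodes: list[tuple[int, int, int]] = []
    for s, e in X.segment_bounds:
        seg = act[:, s:e]
        if seg.shape[1] < min_dur:
            continue
        # cov[n, t]: neuron n is active at every bin of [t, t + min_dur)
        cov = minimum_filter1d(
            seg.astype(np.int8), size=min_dur, axis=1, mode="constant",
            origin=-(min_dur // 2),
        )[:, : seg.shape[1] - min_dur + 1].astype(bool)
        count = cov.sum(axis=0)
        for rs, re in _find_runs(count >= min_neurons):
            episodes.append(
                (s + rs, s + re - 1 + min_dur, int(count[rs:re].max()))
            )
    return AbnormalityReport(persistent_episodes=episodes)


def truncation_cv(occ: OccurrenceSet, K: int) -> np.ndarray:
    """Coefficient of variation of occurrence durations per factor (NaN for
    factors with fewer than 2 occurrences). High values flag sequences that
    truncate at variable points."""
    out = np.full(K, np.nan)
    for k in range(K):
        durs = np.asarray([o.duration for o in occ.by_factor(k)], dtype=float)
        if durs.size >= 2 and durs.mean() > 0:
            out[k] = float(durs.std() / durs.mean())
    return out
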