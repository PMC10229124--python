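"""Shared fixtures: seeded synthetic datasets, preprocessed matrices, and
ground-truth factorizations. Session-scoped where generation is costly."""

from __future__ import annotations

import numpy as np
import pytest

import hvcseq
from hvcseq import preprocess
from hvcseq.containers import Factorization


def ground_truth_factorization(gt, T: int, frame_rate_hz: float = 30.0):
    """Factorization built from the planted exemplars and occurrence times."""
    K = gt.true_W.shape[1]
    H = np.stack([gt.occurrence_indicator(k, T) for k in range(K)]) \
        if K else np.zeros((0, T))
    return Factorization(
        W=gt.true_W, H=H, lam=0.0,
        L_seconds=gt.true_W.shape[2] / frame_rate_hz, seed=0,
        frame_rate_hz=frame_rate_hz,
    )


@pytest.fixture(scope="session")
def pure_sequences_raw():
    return hvcseq.make_fixture("pure_sequences", seed=0)


@pytest.fixture(scope="session")
def pure_sequences_deconv(pure_sequences_raw):
    tm, song, gt = pure_sequences_raw
    deconv, params = preprocess.preprocess_traces(tm)
    return deconv, song, gt


@pytest.fixture(scope="session")
def noise_only_deconv():
    tm, song, gt = hvcseq.make_fixture("noise_only", seed=0)
    deconv, _ = preprocess.preprocess_traces(tm)
    return deconv, song, gt


@pytest.fixture(scope="session")
def learner_days():
    """Two simulated recording days with matched neurons, preprocessed."""
    days = hvcseq.make_fixture("learner_like", seed=0)
    out = []
    for tm, song, gt in days:
        deconv, _ = preprocess.preprocess_traces(tm)
        out.append((deconv, song, gt))
    return out
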