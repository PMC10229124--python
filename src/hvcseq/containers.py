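"""Core in-memory containers shared across the pipeline.

The universal input is a :class:`TraceMatrix` — a neurons x timebins array of
fluorescence (or deconvolved event-rate) values recorded at a fixed frame
rate, concatenated from many short recording files ("segments"/bouts).
Factorizations of that matrix into exemplar sequences and their occurrence
timecourses live in :class:`Factorization`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical order of the eight acoustic song features (Sound Analysis
#: Pro-style), sampled at 1 ms resolution.
SONG_FEATURE_NAMES = (
    "amplitude",
    "entropy",
    "pitch_goodness",
    "aperiodicity",
    "mean_frequency",
    "pitch",
    "frequency_modulation",
    "amplitude_modulation",
)


@dataclass
class TraceMatrix:
    """Neurons x timebins activity matrix with segment (file/bout) structure.

    Parameters
    ----------
    values
        ``(n_neurons, n_timebins)`` float array. Raw fluorescence may take
        any sign; deconvolved event rates must be elementwise non-negative.
    frame_rate_hz
        Imaging frame rate, Hz.
    segment_bounds
        List of ``(start, end)`` bin indices (end-exclusive), one per
        recording file. Must be ordered, non-overlapping, and inside the
        matrix extent.
    neuron_ids
        Stable labels, consistent across days for tracked birds.
    """

    values: np.ndarray
    frame_rate_hz: float
    segment_bounds: list[tuple[int, int]]
    neuron_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (neurons x timebins)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        T = self.values.shape[1]
        if not self.segment_bounds:
            self.segment_bounds = [(0, T)]
        prev_end = 0
        for s, e in self.segment_bounds:
            if not (0 <= s < e <= T):
                raise ValueError(f"segment ({s},{e}) outside matrix extent {T}")
            if s < prev_end:
                raise ValueError("segments must be ordered and non-overlapping")
            prev_end = e
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i}" for i in range(self.values.shape[0])]
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match number of rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_timebins(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_timebins / self.frame_rate_hz

    def segment_slices(self) -> list[slice]:
        return [slice(s, e) for s, e in self.segment_bounds]

    def subset_segments(self, indices: list[int]) -> "TraceMatrix":
        """Concatenate the selected segments into a new TraceMatrix."""
        indices = list(indices)
        parts = [self.values[:, slice(*self.segment_bounds[i])] for i in indices]
        values = np.concatenate(parts, axis=1)
        bounds = []
        pos = 0
        for p in parts:
            bounds.append((pos, pos + p.shape[1]))
            pos += p.shape[1]
        return TraceMatrix(values, self.frame_rate_hz, bounds, list(self.neuron_ids))


@dataclass
class SongFeatureMatrix:
    """Eight acoustic song features at 1 ms resolution (8 x T_ms)."""

    features: np.ndarray
    names: tuple[str, ...] = SONG_FEATURE_NAMES
    rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != 8:
            raise ValueError("features must be 8 x T_ms")
        if tuple(self.names) != SONG_FEATURE_NAMES:
            raise ValueError(
                "song features must be in the canonical order "
                f"{SONG_FEATURE_NAMES}"
            )


@dataclass
class Factorization:
    """Convolutional NMF factorization X ~= W (*) H.

    ``W`` is the neurons x K x Lbins non-negative exemplar tensor, ``H`` the
    K x T non-negative occurrence timecourse matrix. The reconstruction is
    ``X_hat[n, t] = sum_k sum_l W[n, k, l] * H[k, t - l]``.
    """

    W: np.ndarray
    H: np.ndarray
    lam: float
    L_seconds: float
    seed: int
    frame_rate_hz: float
    cost_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 3:
            raise ValueError("W must be 3-D (neurons x K x Lbins)")
        if self.H.ndim != 2 or self.H.shape[0] != self.W.shape[1]:
            raise ValueError("H must be K x T with K matching W")
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("W and H must be elementwise non-negative")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.W.shape[1]

    @property
    def Lbins(self) -> int:
        return self.W.shape[2]

    @property
    def T(self) -> int:
        return self.H.shape[1]


@dataclass
class ReconstructionStats:
    """Power explained and sequenciness of a factorization."""

    power_explained: float
    sequenciness: float
    per_factor_power: np.ndarray
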