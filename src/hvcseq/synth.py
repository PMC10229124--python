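"""Synthetic calcium-imaging datasets with planted sequence structure.

Emulates the statistical structure of single-photon calcium recordings from
singing-bird premotor cortex: K planted sequences of brief per-neuron
transients at fixed lags, probabilistic neuron participation, temporal
jitter, occurrences that truncate early at variable points, occasional
multi-neuron persistent-activity episodes, per-neuron background events,
AR-2 calcium-indicator kernels, additive Gaussian noise, short (~10 s)
recording segments, and 8-channel song-feature traces at 1 ms resolution
coupled to sequence occurrences with controllable strength.

Every simulated dataset is returned together with its full ground truth so
downstream detection, significance, and tracking stages can be validated
without any real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .containers import SongFeatureMatrix, TraceMatrix


def ar2_stable(gamma1: float, gamma2: float) -> bool:
    """True iff the AR-2 process c_t = g1*c_{t-1} + g2*c_{t-2} + s_t is stable
    (roots of 1 - g1*z - g2*z^2 outside the unit circle)."""
    poles = np.roots([1.0, -gamma1, -gamma2])
    return bool(np.all(np.abs(poles) < 1.0))


@dataclass
class SynthConfig:
    """Parameters of the generative model. Defaults emulate a ~100 s session
    of ten 10 s files at 30 Hz with two planted sequences of 30 neurons each,
    spanning ~0.45 s, and a GCaMP6f-like AR-2 kernel (poles 0.9 and 0.5)."""

    n_neurons: int = 60
    n_factors: int = 2
    neurons_per_factor: int = 30
    lag_spacing_s: float = 0.015
    frame_rate_hz: float = 30.0
    segment_length_s: float = 10.0
    n_segments: int = 10
    participation_prob: float = 0.7
    jitter_sd_s: float = 0.01
    truncation_prob: float = 0.0
    truncation_point_dist: tuple[float, float] = (0.3, 1.0)
    persistent_episode_rate: float = 0.0  # episodes per minute
    persistent_min_neurons: int = 3
    persistent_min_dur_s: float = 0.5
    background_event_rate_hz: float = 0.02  # per neuron
    ar_coeffs: tuple[float, float] = (1.4, -0.45)
    noise_sd: float = 0.02
    song_coupling: float | tuple[float, ...] = 0.5  # per-factor, in [0, 1]
    occurrence_rate_hz: float = 0.3  # per factor
    shared_neuron_frac: float = 0.0
    amp_sigma: float = 0.3  # lognormal sd of per-event amplitudes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("participation_prob", "truncation_prob", "shared_neuron_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "persistent_episode_rate", "background_event_rate_hz",
            "occurrence_rate_hz", "jitter_sd_s", "noise_sd", "amp_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        g1, g2 = self.ar_coeffs
        if not ar2_stable(g1, g2):
            raise ValueError(
                f"unstable AR-2 coefficients ({g1}, {g2}): the roots of "
                "1 - g1*z - g2*z^2 must lie outside the unit circle"
            )
        lo, hi = self.truncation_point_dist
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("truncation_point_dist must satisfy 0 < lo <= hi <= 1")

    @property
    def coupling_per_factor(self) -> np.ndarray:
        c = np.atleast_1d(np.asarray(self.song_coupling, dtype=float))
        if c.size == 1:
            c = np.full(self.n_factors, float(c[0]))
        if c.size != self.n_factors:
            raise ValueError("song_coupling must be scalar or per-factor")
        if np.any((c < 0) | (c > 1)):
            raise ValueError("song_coupling values must be in [0, 1]")
        return c


@dataclass
class FactorOccurrences:
    """Planted occurrences of one factor."""

    onsets: np.ndarray  # global bin index of each occurrence onset
    segments: np.ndarray  # segment index of each occurrence
    stop_fractions: np.ndarray  # realised stop fraction in (0, 1]
    participation: np.ndarray  # (n_occurrences, n_members) bool draws


@dataclass
class SynthGroundTruth:
    """Everything the generator planted, for validating downstream stages."""

    true_W: np.ndarray  # neurons x factors x Lbins
    members: np.ndarray  # neurons x factors bool membership
    lags: np.ndarray  # neurons x factors int lag bins (-1 where non-member)
    occurrences: list[FactorOccurrences]
    persistent_episodes: list[tuple[int, int, int, tuple[int, ...]]]
    coupling: np.ndarray  # per-factor song coupling used
    spikes: np.ndarray  # neurons x timebins planted event amplitudes

    def occurrence_indicator(self, k: int, T: int) -> np.ndarray:
        """Binary length-T series, 1 at the onset bin of each occurrence."""
        ind = np.zeros(T)
        ind[self.occurrences[k].onsets] = 1.0
        return ind


def _member_indices(cfg: SynthConfig) -> list[np.ndarray]:
    """Deterministic neuron-to-factor assignment with optional overlap."""
    npf = cfg.neurons_per_factor
    n_shared = int(round(cfg.shared_neuron_frac * npf))
    stride = max(1, npf - n_shared)
    return [
        np.arange(k * stride, k * stride + npf) % cfg.n_neurons
        for k in range(cfg.n_factors)
    ]


def _build_true_w(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    members_list = _member_indices(cfg)
    fr = cfg.frame_rate_hz
    lag_bins = np.round(
        np.arange(cfg.neurons_per_factor) * cfg.lag_spacing_s * fr
    ).astype(int)
    Lbins = int(lag_bins.max()) + 1 if lag_bins.size else 1
    N, K = cfg.n_neurons, cfg.n_factors
    true_W = np.zeros((N, K, Lbins))
    members = np.zeros((N, K), dtype=bool)
    lags = np.full((N, K), -1, dtype=int)
    for k, idx in enumerate(members_list):
        for j, n in enumerate(idx):
            true_W[n, k, lag_bins[j]] = 1.0
            members[n, k] = True
            lags[n, k] = lag_bins[j]
    return true_W, members, lags, Lbins


def simulate(
    config: SynthConfig,
) -> tuple[TraceMatrix, SongFeatureMatrix, SynthGroundTruth]:
    """Generate one dataset: traces = (planted sequences + persistent
    episodes + background events) convolved with the AR-2 kernel, plus
    Gaussian noise, clipped at zero. Identical seed, identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fr = cfg.frame_rate_hz
    seg_bins = int(round(cfg.segment_length_s * fr))
    T = seg_bins * cfg.n_segments
    N, K = cfg.n_neurons, cfg.n_factors

    true_W, members, lags, Lbins = _build_true_w(cfg)
    members_list = _member_indices(cfg)
    lag_bins_template = np.round(
        np.arange(cfg.neurons_per_factor) * cfg.lag_spacing_s * fr
    ).astype(int)
    max_lag = int(lag_bins_template.max()) if lag_bins_template.size else 0

    spikes = np.zeros((N, T))
    occurrences: list[FactorOccurrences] = []

    def _amp(size=None):
        if cfg.amp_sigma == 0:
            return np.ones(size) if size is not None else 1.0
        return rng.lognormal(mean=0.0, sigma=cfg.amp_sigma, size=size)

    # --- planted sequence occurrences ----------------------------------
    for k in range(K):
        onsets_all, segs_all, stops_all, part_all = [], [], [], []
        for seg in range(cfg.n_segments):
            n_occ = rng.poisson(cfg.occurrence_rate_hz * cfg.segment_length_s)
            slots = seg_bins - Lbins
            if slots <= 0:
                continue
            placed: list[int] = []
            for _ in range(n_occ):
                for _try in range(20):
                    cand = int(rng.integers(0, slots + 1))
                    if all(abs(cand - p) >= Lbins for p in placed):
                        placed.append(cand)
                        break
            for onset_local in sorted(placed):
                onset = seg * seg_bins + onset_local
                if cfg.truncation_prob > 0 and rng.random() < cfg.truncation_prob:
                    lo, hi = cfg.truncation_point_dist
                    f_stop = float(rng.uniform(lo, hi))
                else:
                    f_stop = 1.0
                part = rng.random(cfg.neurons_per_factor) < cfg.participation_prob
                for j, n in enumerate(members_list[k]):
                    if not part[j]:
                        continue
                    lag = lag_bins_template[j]
                    if max_lag > 0 and lag > f_stop * max_lag:
                        continue
                    jit = int(round(rng.normal(0.0, cfg.jitter_sd_s * fr))) \
                        if cfg.jitter_sd_s > 0 else 0
                    t = onset + lag + jit
                    seg_lo, seg_hi = seg * seg_bins, (seg + 1) * seg_bins
                    t = min(max(t, seg_lo), seg_hi - 1)
                    spikes[n, t] += _amp()
                onsets_all.append(onset)
                segs_all.append(seg)
                stops_all.append(f_stop)
                part_all.append(part)
        occurrences.append(
            FactorOccurrences(
                onsets=np.asarray(onsets_all, dtype=int),
                segments=np.asarray(segs_all, dtype=int),
                stop_fractions=np.asarray(stops_all, dtype=float),
                participation=(
                    np.asarray(part_all, dtype=bool)
                    if part_all
                    else np.zeros((0, cfg.neurons_per_factor), dtype=bool)
                ),
            )
        )

    # --- persistent-activity episodes ----------------------------------
    episodes: list[tuple[int, int, int, tuple[int, ...]]] = []
    if cfg.persistent_episode_rate > 0:
        total_min = cfg.n_segments * cfg.segment_length_s / 60.0
        n_ep = rng.poisson(cfg.persistent_episode_rate * total_min)
        min_dur = int(round(cfg.persistent_min_dur_s * fr))
        for _ in range(n_ep):
            seg = int(rng.integers(0, cfg.n_segments))
            dur = int(rng.integers(min_dur, 2 * min_dur + 1))
            if dur >= seg_bins:
                dur = seg_bins - 1
            onset_local = int(rng.integers(0, seg_bins - dur))
            onset = seg * seg_bins + onset_local
            n_cells = int(
                rng.integers(cfg.persistent_min_neurons, cfg.persistent_min_neurons + 3)
            )
            cells = tuple(int(c) for c in rng.choice(N, size=n_cells, replace=False))
            for c in cells:
                spikes[c, onset : onset + dur] += 0.25
            episodes.append((seg, onset, onset + dur, cells))

    # --- background events ----------------------------------------------
    if cfg.background_event_rate_hz > 0:
        total_s = T / fr
        for n in range(N):
            n_bg = rng.poisson(cfg.background_event_rate_hz * total_s)
            if n_bg:
                bins = rng.integers(0, T, size=n_bg)
                np.add.at(spikes[n], bins, _amp(n_bg))

    # --- AR-2 convolution + noise, per independent segment ---------------
    g1, g2 = cfg.ar_coeffs
    traces = np.empty_like(spikes)
    for seg in range(cfg.n_segments):
        sl = slice(seg * seg_bins, (seg + 1) * seg_bins)
        traces[:, sl] = lfilter([1.0], [1.0, -g1, -g2], spikes[:, sl], axis=1)
    if cfg.noise_sd > 0:
        traces = traces + rng.normal(0.0, cfg.noise_sd, size=traces.shape)
    traces = np.clip(traces, 0.0, None)

    bounds = [(s * seg_bins, (s + 1) * seg_bins) for s in range(cfg.n_segments)]
    tm = TraceMatrix(traces, fr, bounds)

    # --- song features ---------------------------------------------------
    coupling = cfg.coupling_per_factor
    song = _make_song_features(cfg, occurrences, coupling, Lbins, T, rng)

    gt = SynthGroundTruth(
        true_W=true_W,
        members=members,
        lags=lags,
        occurrences=occurrences,
        persistent_episodes=episodes,
        coupling=coupling,
        spikes=spikes,
    )
    return tm, song, gt


def _make_song_features(
    cfg: SynthConfig,
    occurrences: list[FactorOccurrences],
    coupling: np.ndarray,
    Lbins: int,
    T: int,
    rng: np.random.Generator,
) -> SongFeatureMatrix:
    """8 channels at 1 ms: lowpass-filtered mixtures of occurrence indicators
    (weighted by coupling) and independent white noise. No attempt at
    acoustically realistic spectra."""
    fr = cfg.frame_rate_hz
    T_ms = int(round(T / fr * 1000))
    K = cfg.n_factors
    ind_ms = np.zeros((max(K, 1), T_ms))
    span_ms = int(round(Lbins / fr * 1000))
    for k in range(K):
        for onset, f_stop in zip(
            occurrences[k].onsets, occurrences[k].stop_fractions
        ):
            a = int(round(onset / fr * 1000))
            b = min(T_ms, a + max(1, int(round(f_stop * span_ms))))
            ind_ms[k, a:b] = 1.0
    mix = rng.uniform(0.5, 1.0, size=(8, max(K, 1)))
    feats = np.empty((8, T_ms))
    for c in range(8):
        signal = np.zeros(T_ms)
        for k in range(K):
            signal += coupling[k] * mix[c, k] * ind_ms[k]
        signal = signal + rng.normal(0.0, 1.0, size=T_ms)
        feats[c] = gaussian_filter1d(signal, sigma=10.0)
    return SongFeatureMatrix(feats)


# ---------------------------------------------------------------------------
# Canonical presets for tests and worked examples
# ---------------------------------------------------------------------------

PRESETS = (
    "pure_sequences",
    "pure_synchrony",
    "noise_only",
    "isolate_like",
    "learner_like",
)


def preset_config(preset_name: str, seed: int = 0, **overrides) -> SynthConfig:
    """Config for a named canonical dataset (see :func:`make_fixture`)."""
    base = dict(seed=seed)
    if preset_name == "pure_sequences":
        base.update(
            noise_sd=0.0, jitter_sd_s=0.0, truncation_prob=0.0,
            participation_prob=1.0, background_event_rate_hz=0.0,
            persistent_episode_rate=0.0, amp_sigma=0.0, song_coupling=0.5,
        )
    elif preset_name == "pure_synchrony":
        base.update(
            lag_spacing_s=0.0, noise_sd=0.0, jitter_sd_s=0.0,
            truncation_prob=0.0, participation_prob=1.0,
            background_event_rate_hz=0.0, persistent_episode_rate=0.0,
            amp_sigma=0.0, song_coupling=0.5,
        )
    elif preset_name == "noise_only":
        base.update(
            n_factors=0, neurons_per_factor=0, background_event_rate_hz=0.2,
            noise_sd=0.02, song_coupling=0.0, persistent_episode_rate=0.0,
        )
    elif preset_name == "isolate_like":
        base.update(
            truncation_prob=0.5, persistent_episode_rate=1.0,
            participation_prob=0.7, jitter_sd_s=0.01,
            background_event_rate_hz=0.05, noise_sd=0.02, song_coupling=0.4,
        )
    elif preset_name == "learner_like":
        base.update(
            participation_prob=0.9, truncation_prob=0.0, jitter_sd_s=0.005,
            background_event_rate_hz=0.02, noise_sd=0.02,
            song_coupling=(0.1, 0.5),
        )
    else:
        raise ValueError(f"unknown preset {preset_name!r}; choose from {PRESETS}")
    base.update(overrides)
    return SynthConfig(**base)


def make_fixture(preset_name: str, seed: int = 0, **overrides):
    """Seeded canonical dataset(s) for tests and examples.

    ``learner_like`` returns a list of two (traces, song, ground truth)
    tuples — simulated recording days with matched neuron identities, where
    the first factor's song coupling rises from 0.1 (day 1) to 0.8 (day 2),
    emulating an initially latent sequence becoming song-locked.
    All other presets return a single (traces, song, ground truth) tuple.
    """
    if preset_name == "learner_like":
        cfg1 = preset_config(preset_name, seed=seed, **overrides)
        cfg2 = replace(cfg1, song_coupling=(0.8, 0.5), seed=seed + 10007)
        return [simulate(cfg1), simulate(cfg2)]
    return simulate(preset_config(preset_name, seed=seed, **overrides))
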