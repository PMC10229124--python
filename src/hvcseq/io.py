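"""HDF5 and delimited-text persistence for traces, song features,
factorizations, ground truth, and occurrence tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SONG_FEATURE_NAMES, Factorization, SongFeatureMatrix, TraceMatrix
from .metrics import OccurrenceSet
from .synth import FactorOccurrences, SynthGroundTruth


def save_traces(path: str | Path, tm: TraceMatrix) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("traces", data=tm.values)
        h5.create_dataset("frame_rate", data=tm.frame_rate_hz)
        h5.create_dataset("segment_bounds", data=np.asarray(tm.segment_bounds))
        h5.create_dataset(
            "neuron_ids",
            data=np.asarray(tm.neuron_ids, dtype=h5py.string_dtype()),
        )


def load_traces(path: str | Path) -> TraceMatrix:
    with h5py.File(path, "r") as h5:
        return TraceMatrix(
            values=h5["traces"][()],
            frame_rate_hz=float(h5["frame_rate"][()]),
            segment_bounds=[tuple(b) for b in h5["segment_bounds"][()]],
            neuron_ids=[s.decode() for s in h5["neuron_ids"][()]],
        )


def save_traces_text(path: str | Path, tm: TraceMatrix) -> None:
    """Delimited-text export (one row per neuron); segment bounds go to a
    sidecar .segments.tsv file."""
    path = Path(path)
    np.savetxt(path, tm.values, delimiter="\t")
    np.savetxt(
        path.with_suffix(path.suffix + ".segments.tsv"),
        np.asarray(tm.segment_bounds, dtype=int), fmt="%d", delimiter="\t",
    )


def save_song(path: str | Path, song: SongFeatureMatrix) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("features", data=song.features)
        h5.create_dataset("feature_rate", data=song.rate_hz)
        h5.create_dataset(
            "feature_names",
            data=np.asarray(song.names, dtype=h5py.string_dtype()),
        )


def load_song(path: str | Path) -> SongFeatureMatrix:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as h5:
            return SongFeatureMatrix(features=h5["features"][()])
    # Delimited text: 8 columns in canonical order, one row per ms.
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [n for n in SONG_FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"song feature file missing columns {missing}")
    return SongFeatureMatrix(features=df[list(SONG_FEATURE_NAMES)].to_numpy().T)


def save_factorization(path: str | Path, f: Factorization) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("W", data=f.W)
        h5.create_dataset("H", data=f.H)
        h5.create_dataset("lambda", data=f.lam)
        h5.create_dataset("L_seconds", data=f.L_seconds)
        h5.create_dataset("seed", data=f.seed)
        h5.create_dataset("frame_rate", data=f.frame_rate_hz)
        h5.create_dataset("cost_history", data=f.cost_history)


def load_factorization(path: str | Path) -> Factorization:
    with h5py.File(path, "r") as h5:
        return Factorization(
            W=h5["W"][()], H=h5["H"][()], lam=float(h5["lambda"][()]),
            L_seconds=float(h5["L_seconds"][()]), seed=int(h5["seed"][()]),
            frame_rate_hz=float(h5["frame_rate"][()]),
            cost_history=h5["cost_history"][()],
        )


def save_ground_truth(path: str | Path, gt: SynthGroundTruth) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("true_W", data=gt.true_W)
        h5.create_dataset("members", data=gt.members)
        h5.create_dataset("lags", data=gt.lags)
        h5.create_dataset("coupling", data=gt.coupling)
        h5.create_dataset("spikes", data=gt.spikes)
        for k, occ in enumerate(gt.occurrences):
            g = h5.create_group(f"factor_{k}")
            g.create_dataset("onsets", data=occ.onsets)
            g.create_dataset("segments", data=occ.segments)
            g.create_dataset("stop_fractions", data=occ.stop_fractions)
            g.create_dataset("participation", data=occ.participation)
        ep = h5.create_group("persistent_episodes")
        for i, (seg, on, off, cells) in enumerate(gt.persistent_episodes):
            ep.create_dataset(f"ep_{i}", data=np.asarray([seg, on, off]))
            ep.create_dataset(f"ep_{i}_cells", data=np.asarray(cells))


def load_ground_truth(path: str | Path) -> SynthGroundTruth:
    with h5py.File(path, "r") as h5:
        K = h5["true_W"].shape[1]
        occurrences = []
        for k in range(K):
            g = h5[f"factor_{k}"]
            occurrences.append(
                FactorOccurrences(
                    onsets=g["onsets"][()], segments=g["segments"][()],
                    stop_fractions=g["stop_fractions"][()],
                    participation=g["participation"][()],
                )
            )
        episodes = []
        ep = h5["persistent_episodes"]
        i = 0
        while f"ep_{i}" in ep:
            seg, on, off = ep[f"ep_{i}"][()]
            cells = tuple(int(c) for c in ep[f"ep_{i}_cells"][()])
            episodes.append((int(seg), int(on), int(off), cells))
            i += 1
        return SynthGroundTruth(
            true_W=h5["true_W"][()], members=h5["members"][()],
            lags=h5["lags"][()], occurrences=occurrences,
            persistent_episodes=episodes, coupling=h5["coupling"][()],
            spikes=h5["spikes"][()],
        )


def occurrence_table(occ: OccurrenceSet, frame_rate_hz: float,
                     segment_bounds: list[tuple[int, int]]) -> pd.DataFrame:
    """Tidy table of detected occurrences (factor, bout, onset_s, duration_s)."""
    starts = np.asarray([s for s, _ in segment_bounds])
    rows = []
    for o in occ.occurrences:
        bout = int(np.searchsorted(starts, o.onset, side="right") - 1)
        rows.append(
            dict(
                factor=o.factor, bout=bout,
                onset_s=o.onset / frame_rate_hz,
                duration_s=o.duration / frame_rate_hz,
            )
        )
    return pd.DataFrame(rows, columns=["factor", "bout", "onset_s", "duration_s"])
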