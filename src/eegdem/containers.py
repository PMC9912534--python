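"""In-memory containers for recordings and epoched data, plus array I/O.

Recordings and epoch sets are serialized as compressed ``.npz`` archives with
a JSON sidecar carrying the subject id, sampling rate and channel names, so
every pipeline stage can be run (and tested) in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import MONTAGE_16


@dataclass
class Recording:
    """One subject's continuous multichannel EEG, in microvolts.

    ``artifact_truth`` is only populated by the synthetic generator: a boolean
    per-sample mask of the samples it corrupted with spike artifacts. Real
    recordings carry ``None``.
    """

    signal: np.ndarray            # (n_channels, n_samples), microvolts
    fs: float
    channel_names: tuple[str, ...] = MONTAGE_16
    subject_id: str = "anonymous"
    artifact_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signal.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, signal: np.ndarray) -> "Recording":
        return Recording(signal, self.fs, self.channel_names, self.subject_id,
                         self.artifact_truth)


@dataclass
class ArtifactMask:
    """Window-wise artifact bookkeeping over one recording."""

    window_starts: np.ndarray     # sample index of each window start
    window_length: int            # samples per window (last may be truncated)
    artifact_fraction: np.ndarray
    excluded: np.ndarray          # bool per window
    fraction_threshold: float

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)


@dataclass
class EpochSet:
    """Cleaned fixed-length epochs for one subject.

    ``offsets`` records each epoch's starting sample in the original
    recording (provenance for grouped splits and audits).
    """

    data: np.ndarray              # (M, n_channels, epoch_samples)
    fs: float
    subject_id: str = "anonymous"
    channel_names: tuple[str, ...] = MONTAGE_16
    offsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_samples(self) -> int:
        return self.data.shape[2]


def save_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, signal=rec.signal.astype(np.float32))
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "kind": "recording",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_recording(path: str | Path) -> Recording:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as npz:
        signal = npz["signal"].astype(float)
    return Recording(signal, meta["fs"], tuple(meta["channel_names"]),
                     meta["subject_id"])


def save_epochs(es: EpochSet, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    np.savez_compressed(path, data=es.data.astype(np.float32),
                        offsets=es.offsets.astype(np.int64))
    sidecar = {
        "subject_id": es.subject_id,
        "fs": es.fs,
        "channel_names": list(es.channel_names),
        "kind": "epochs",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path).with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as npz:
        data = npz["data"].astype(float)
        offsets = npz["offsets"]
    return EpochSet(data, meta["fs"], meta["subject_id"],
                    tuple(meta["channel_names"]), offsets)
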