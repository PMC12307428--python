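"""Core epoch containers and plain-text collection I/O.

An :class:`EEGSegment` is one labelled 1-s epoch of 19-channel EEG sampled
at 1000 Hz.  A :class:`SegmentCollection` bundles the epochs of one subject
together with channel names and per-class counts.

Collections serialize to two CSV files (``<stem>_meta.csv`` holding one row
per segment and ``<stem>_data.csv`` holding one row per segment/channel
pair with the 1000 samples as columns) so that fixtures stay text-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 19
N_SAMPLES = 1000
FS = 1000
CLASS_IDS = (1, 2, 3, 4, 5, 6)
#: class 6 is the no-mental-task (idle) baseline
NOMT_CLASS = 6

#: Fixed 10-20 montage order used for channel indices 1..19 throughout the
#: package.  The ordering is this repository's convention; all channel maps
#: and distribution tables index channels 1-19 in this order.
CHANNEL_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class EEGSegment:
    """One labelled 19 x 1000 epoch (microvolt scale)."""

    data: np.ndarray
    label: int
    subject: str = "S?"
    segment_id: int = 0
    fs: int = FS

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape != (N_CHANNELS, N_SAMPLES):
            raise ValueError(
                f"segment data must be {N_CHANNELS}x{N_SAMPLES}, got {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("segment data contains non-finite values")
        if self.fs != FS:
            raise ValueError(f"sampling rate must be {FS} Hz, got {self.fs}")
        if self.label not in CLASS_IDS:
            raise ValueError(f"label must be in {CLASS_IDS}, got {self.label}")
        object.__setattr__(self, "data", data)

    def channel(self, index: int) -> np.ndarray:
        """Return one channel's samples; ``index`` is 1-based (1..19)."""
        if not 1 <= index <= N_CHANNELS:
            raise ValueError(f"channel index must be in [1, {N_CHANNELS}]")
        return self.data[index - 1]


@dataclass
class SegmentCollection:
    """Ordered segments of one subject plus channel metadata."""

    segments: list[EEGSegment]
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    subject: str = "S?"

    def __post_init__(self) -> None:
        if len(self.channel_names) != N_CHANNELS:
            raise ValueError("need exactly 19 channel names")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in CLASS_IDS}
        for seg in self.segments:
            counts[seg.label] += 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.array([seg.label for seg in self.segments], dtype=int)

    def is_balanced(self) -> bool:
        counts = set(self.class_counts.values())
        return len(counts) == 1


def write_collection(collection: SegmentCollection, stem: str | Path) -> tuple[Path, Path]:
    """Write a collection to ``<stem>_meta.csv`` + ``<stem>_data.csv``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta_path = stem.with_name(stem.name + "_meta.csv")
    data_path = stem.with_name(stem.name + "_data.csv")

    meta = pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in collection.segments],
            "subject": [s.subject for s in collection.segments],
            "label": [s.label for s in collection.segments],
            "fs": [s.fs for s in collection.segments],
        }
    )
    header = pd.DataFrame({"channel_names": list(collection.channel_names)})
    meta["collection_subject"] = collection.subject
    meta.to_csv(meta_path, index=False)
    header.to_csv(stem.with_name(stem.name + "_channels.csv"), index=False)

    rows = []
    for seg in collection.segments:
        for ch in range(N_CHANNELS):
            rows.append((seg.segment_id, ch + 1, *seg.data[ch]))
    cols = ["segment_id", "channel", *[f"s{i}" for i in range(N_SAMPLES)]]
    pd.DataFrame(rows, columns=cols).to_csv(data_path, index=False, float_format="%.10g")
    return meta_path, data_path


def read_collection(stem: str | Path) -> SegmentCollection:
    """Read a collection previously written by :func:`write_collection`."""
    stem = Path(stem)
    meta_path = stem.with_name(stem.name + "_meta.csv")
    data_path = stem.with_name(stem.name + "_data.csv")
    chan_path = stem.with_name(stem.name + "_channels.csv")
    for p in (meta_path, data_path):
        if not p.exists():
            raise FileNotFoundError(p)

    meta = pd.read_csv(meta_path)
    data = pd.read_csv(data_path)
    if chan_path.exists():
        channel_names = tuple(pd.read_csv(chan_path)["channel_names"])
    else:
        channel_names = CHANNEL_NAMES

    sample_cols = [f"s{i}" for i in range(N_SAMPLES)]
    segments = []
    for _, row in meta.iterrows():
        block = data[data["segment_id"] == row["segment_id"]].sort_values("channel")
        mat = block[sample_cols].to_numpy(dtype=float)
        segments.append(
            EEGSegment(
                data=mat,
                label=int(row["label"]),
                subject=str(row["subject"]),
                segment_id=int(row["segment_id"]),
                fs=int(row["fs"]),
            )
        )
    subject = str(meta["collection_subject"].iloc[0]) if len(meta) else "S?"
    return SegmentCollection(segments=segments, channel_names=channel_names, subject=subject)
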