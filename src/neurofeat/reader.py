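"""Optional adapter for the public motor-imagery recordings.

Reads the published matrix-container files (MATLAB ``.mat`` with a single
struct ``o`` carrying ``data`` (samples x channels), ``marker`` (per-sample
event code) and ``sampFreq``) and cuts 1-s epochs at marker onsets.  Marker
codes 1-5 label the five finger classes; epochs cut from no-task recordings
(or an explicit idle code) become class 6.

This module is import-isolated: nothing else in the package imports it, so
the pipeline builds and tests without the external download.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .segments import FS, N_CHANNELS, N_SAMPLES, NOMT_CLASS, EEGSegment, SegmentCollection

FINGER_CODES = (1, 2, 3, 4, 5)


class ContainerFormatError(ValueError):
    """Raised when the container file lacks an expected field."""


def read_source_container(
    path: str | Path,
    nomt: bool = False,
    subject: str | None = None,
) -> SegmentCollection:
    """Cut labelled 1-s epochs from one recording container.

    Parameters
    ----------
    path
        A ``.mat`` file with the ``o.data`` / ``o.marker`` layout.
    nomt
        If True, the file is treated as an idle-state recording and
        non-overlapping 1-s epochs labelled class 6 are cut instead of
        marker-aligned ones.
    subject
        Subject identifier; defaults to the file stem.
    """
    from scipy.io import loadmat  # deferred: only needed for real data

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    if "o" not in mat:
        raise ContainerFormatError(f"{path.name}: missing top-level struct 'o'")
    o = mat["o"]
    for fieldname in ("data", "marker", "sampFreq"):
        if not hasattr(o, fieldname):
            raise ContainerFormatError(f"{path.name}: missing field 'o.{fieldname}'")
    if int(o.sampFreq) != FS:
        raise ContainerFormatError(
            f"{path.name}: sampFreq {o.sampFreq}, expected {FS}"
        )
    data = np.asarray(o.data, dtype=float)
    if data.ndim != 2 or data.shape[1] < N_CHANNELS:
        raise ContainerFormatError(
            f"{path.name}: data shape {data.shape} lacks {N_CHANNELS} channels"
        )
    data = data[:, :N_CHANNELS]  # drop any auxiliary columns (e.g. sync)
    marker = np.asarray(o.marker, dtype=int).ravel()
    subject = subject or path.stem

    segments: list[EEGSegment] = []
    sid = 0
    if nomt:
        for start in range(0, data.shape[0] - N_SAMPLES + 1, N_SAMPLES):
            segments.append(
                EEGSegment(
                    data=data[start : start + N_SAMPLES].T,
                    label=NOMT_CLASS,
                    subject=subject,
                    segment_id=sid,
                )
            )
            sid += 1
    else:
        onsets = np.flatnonzero(
            (marker[1:] != marker[:-1]) & np.isin(marker[1:], FINGER_CODES)
        ) + 1
        for start in onsets:
            if start + N_SAMPLES > data.shape[0]:
                continue
            segments.append(
                EEGSegment(
                    data=data[start : start + N_SAMPLES].T,
                    label=int(marker[start]),
                    subject=subject,
                    segment_id=sid,
                )
            )
            sid += 1
    return SegmentCollection(segments=segments, subject=subject)
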