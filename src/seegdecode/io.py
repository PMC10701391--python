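"""Session I/O: NumPy array bundles and BIDS-style events files.

A Recording is written as a compressed ``.npz`` bundle with keys ``data``
(channels x samples, float64), ``sampling_rate_hz``, ``channel_names`` and
``anatomical_labels``. Events go to a tab-separated file with the BIDS
events columns ``onset`` (seconds), ``duration`` (seconds) and ``trial_type``
plus ``hand``, ``task`` and ``onset_sample``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synthetic import EventTable, Recording


def save_recording(recording: Recording, path: str | Path) -> None:
    np.savez_compressed(
        path,
        data=recording.data,
        sampling_rate_hz=np.float64(recording.sampling_rate_hz),
        channel_names=np.array(recording.channel_names),
        anatomical_labels=np.array(recording.anatomical_labels),
    )


def load_recording(path: str | Path) -> Recording:
    with np.load(path, allow_pickle=False) as f:
        return Recording(
            data=f["data"],
            sampling_rate_hz=float(f["sampling_rate_hz"]),
            channel_names=[str(s) for s in f["channel_names"]],
            anatomical_labels=[str(s) for s in f["anatomical_labels"]],
        )


def save_events(events: EventTable, sampling_rate_hz: float,
                path: str | Path, trial_duration_s: float = 3.0) -> None:
    df = pd.DataFrame({
        "onset": events["onset_sample"] / sampling_rate_hz,
        "duration": trial_duration_s,
        "trial_type": events["condition"],
        "hand": events["hand"],
        "task": events["task"],
        "onset_sample": events["onset_sample"],
    })
    df.to_csv(path, sep="\t", index=False)


def load_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(pd.DataFrame({
        "onset_sample": df["onset_sample"].astype(int),
        "condition": df["trial_type"],
        "hand": df["hand"],
        "task": df["task"],
    }))


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    np.savez_compressed(
        path,
        data=epochs.data,
        labels=np.array(epochs.labels, dtype=str),
        band=np.array(epochs.band),
        sampling_rate_hz=np.float64(epochs.sampling_rate_hz),
        channel_names=np.array(epochs.channel_names
                               if epochs.channel_names is not None else []),
    )


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as f:
        names = [str(s) for s in f["channel_names"]]
        return EpochSet(
            data=f["data"],
            labels=np.array([str(s) for s in f["labels"]]),
            band=str(f["band"]),
            sampling_rate_hz=float(f["sampling_rate_hz"]),
            channel_names=names or None,
        )
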