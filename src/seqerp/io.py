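"""Readers and writers: BrainVision recordings, the plain tabular epoch
format (TSV matrix + TSV trial metadata) and behavioral trial tables.

Tabular epoch format: the matrix file has one row per sample and one column
per trial, with a leading ``time_ms`` column; the sidecar metadata file has
one row per trial with columns participant, group, task, trial,
sequence_type, disruption_position, response_correct (and optionally
rejected).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EpochSet

REQUIRED_META = ("participant", "group", "task", "trial", "sequence_type",
                 "response_correct")


def read_brainvision(header_path: str | Path, channel: str = "Pz"
                     ) -> ContinuousRecording:
    """Read a BrainVision (.vhdr/.vmrk/.eeg) recording via MNE.

    Returns the selected channel (default Pz) in µV together with the event
    markers as (sample index, label) rows.
    """
    import mne  # local import: slow to load, only needed for this reader

    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    raw = mne.io.read_raw_brainvision(header_path, preload=True,
                                      verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not in recording (has {raw.ch_names})")
    data_uv = raw.get_data(picks=[channel])[0] * 1e6  # volts → µV
    ann = raw.annotations
    events = pd.DataFrame({
        "sample": np.round(ann.onset * raw.info["sfreq"]).astype(int),
        "label": [str(d) for d in ann.description],
    })
    if len(events):
        # Drop MNE's synthetic "New Segment" bookkeeping marker.
        events = events[~events["label"].str.startswith("New Segment")]
    events = events.reset_index(drop=True)
    return ContinuousRecording(data=data_uv, sample_rate=raw.info["sfreq"],
                               events=events, channel=channel)


def write_epochs_tsv(epochs: EpochSet, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    """Write one EpochSet in the tabular epoch format (rows = samples)."""
    mat = pd.DataFrame(epochs.data.T,
                       columns=[f"trial_{t}" for t in epochs.trials["trial"]])
    mat.insert(0, "time_ms", epochs.times)
    mat.to_csv(matrix_path, sep="\t", index=False, float_format="%.6g")
    meta = epochs.trials.copy()
    meta.insert(0, "participant", epochs.participant_id)
    meta.insert(1, "group", epochs.group)
    meta.insert(2, "task", epochs.task)
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_epochs_tsv(matrix_path: str | Path, metadata_path: str | Path
                    ) -> EpochSet:
    """Read one EpochSet from the tabular epoch format."""
    mat = pd.read_csv(matrix_path, sep="\t")
    if "time_ms" not in mat.columns:
        raise ValueError("matrix file must have a time_ms column")
    times = mat["time_ms"].to_numpy(dtype=float)
    data = mat.drop(columns=["time_ms"]).to_numpy(dtype=float).T
    meta = pd.read_csv(metadata_path, sep="\t")
    missing = [c for c in REQUIRED_META if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    for col in ("participant", "group", "task"):
        if meta[col].nunique() != 1:
            raise ValueError(f"metadata column {col} must be constant "
                             "within one epoch file")
    if "rejected" not in meta.columns:
        meta["rejected"] = False
    if "disruption_position" not in meta.columns:
        meta["disruption_position"] = "none"
    trials = meta.drop(columns=["participant", "group", "task"])
    step = np.diff(times)
    if times.size > 1 and not np.allclose(step, step[0], atol=1e-6):
        raise ValueError("time axis is not uniform")
    sample_rate = 1000.0 / step[0] if times.size > 1 else 1.0
    return EpochSet(data=data, times=times, sample_rate=sample_rate,
                    participant_id=str(meta["participant"].iloc[0]),
                    group=str(meta["group"].iloc[0]),
                    task=str(meta["task"].iloc[0]), trials=trials)


def write_behavior_tsv(behavior: pd.DataFrame, path: str | Path) -> None:
    behavior.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_behavior_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"participant", "group", "task", "trial", "sequence_type",
                "response", "correct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    return table
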