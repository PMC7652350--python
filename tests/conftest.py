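"""Shared fixtures: hand-built epoch sets and a minimal BrainVision writer.

All fixture data are generated programmatically at test time.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from seqerp.containers import EpochSet


def make_epoch_set(data, sample_rate=500.0, t_start=-250.0,
                   sequence_type=None, response_correct=None, rejected=None,
                   participant_id="P01", group="TD", task="visual"):
    """EpochSet around a raw (n_trials, n_samples) array with simple
    defaults for the trial metadata."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, t = data.shape
    step = 1000.0 / sample_rate
    times = t_start + step * np.arange(t)
    if sequence_type is None:
        sequence_type = ["disrupted" if i % 2 == 0 else "intact"
                         for i in range(n)]
    trials = pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "sequence_type": sequence_type,
        "disruption_position": ["10" if s == "disrupted" else "none"
                                for s in sequence_type],
        "response_correct": (np.ones(n, dtype=bool) if response_correct
                             is None else response_correct),
        "rejected": (np.zeros(n, dtype=bool) if rejected is None
                     else rejected),
    })
    return EpochSet(data=data, times=times, sample_rate=sample_rate,
                    participant_id=participant_id, group=group, task=task,
                    trials=trials)


def write_brainvision(dirpath, name, data_uv, sfreq, markers,
                      ch_name="Pz") -> Path:
    """Write a minimal single-channel BrainVision triplet (synthetic test
    fixture): IEEE float32 multiplexed .eeg with text .vhdr/.vmrk."""
    d = Path(dirpath)
    (d / f"{name}.vhdr").write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={name}.eeg\n"
        f"MarkerFile={name}.vmrk\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        "NumberOfChannels=1\n"
        f"SamplingInterval={1e6 / sfreq:.0f}\n"
        "[Binary Infos]\n"
        "BinaryFormat=IEEE_FLOAT_32\n"
        "[Channel Infos]\n"
        f"Ch1={ch_name},,1,µV\n")
    lines = ["Brain Vision Data Exchange Marker File, Version 1.0",
             "[Common Infos]", f"DataFile={name}.eeg", "[Marker Infos]",
             "Mk1=New Segment,,1,1,0,00000000000000000000"]
    for i, (samp, lab) in enumerate(markers, start=2):
        # BrainVision marker positions are 1-based
        lines.append(f"Mk{i}=Stimulus,{lab},{samp + 1},1,0")
    (d / f"{name}.vmrk").write_text("\n".join(lines) + "\n")
    np.asarray(data_uv, dtype="<f4").tofile(d / f"{name}.eeg")
    return d / f"{name}.vhdr"


@pytest.fixture
def rng():
    return np.random.default_rng(0)
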