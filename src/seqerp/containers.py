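"""In-memory containers for single-channel epoched EEG and condition averages.

All amplitudes are in microvolts (µV) and all times in milliseconds relative
to the alignment point of the epoch (stimulus onset, possibly shifted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Columns every trial-metadata table must carry.
TRIAL_COLUMNS = ("trial", "sequence_type", "disruption_position",
                 "response_correct", "rejected")

SEQUENCE_TYPES = ("intact", "disrupted")


@dataclass
class ContinuousRecording:
    """A continuous single-channel EEG record with event markers.

    ``data`` is a 1-D µV array; ``events`` holds one row per marker with
    columns ``sample`` (0-based index into ``data``) and ``label``.
    """

    data: np.ndarray
    sample_rate: float
    events: pd.DataFrame
    channel: str = "Pz"
    reference: str = "linked mastoids"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("continuous data must be one channel (1-D)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class EpochSet:
    """Per-participant, per-task collection of single-channel epochs.

    ``data`` has shape (n_trials, n_samples); ``trials`` is a metadata table
    aligned row-for-row with ``data`` carrying at least ``sequence_type``
    (intact/disrupted), ``disruption_position`` (10, 11 or 'none'),
    ``response_correct`` and ``rejected`` flags.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    participant_id: str
    group: str
    task: str
    trials: pd.DataFrame
    channel: str = "Pz"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[1] != self.times.size:
            raise ValueError(
                f"data has {self.data.shape[1]} samples but times has "
                f"{self.times.size}")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("trial metadata rows must match data rows")
        step = 1000.0 / self.sample_rate
        if self.times.size > 1:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0) or not np.allclose(diffs, step, atol=1e-6):
                raise ValueError(
                    "times must be strictly increasing with uniform step "
                    f"{step} ms")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial metadata missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def usable_mask(self, correct_only: bool = False) -> np.ndarray:
        """Boolean mask of trials that survive rejection (and, optionally,
        require a correct behavioral response)."""
        mask = ~self.trials["rejected"].to_numpy(dtype=bool)
        if correct_only:
            mask &= self.trials["response_correct"].to_numpy(dtype=bool)
        return mask

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[mask],
                       trials=self.trials.loc[mask].reset_index(drop=True))

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(),
                       trials=self.trials.copy(deep=True))


@dataclass
class ERPWaveform:
    """A per-participant condition average (event-related potential)."""

    values: np.ndarray
    times: np.ndarray
    n_trials: int
    participant_id: str
    group: str
    task: str
    sequence_type: str
    channel: str = "Pz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have the same shape")


def difference_wave(disrupted: ERPWaveform, intact: ERPWaveform) -> ERPWaveform:
    """Disrupted − intact difference waveform for one participant."""
    if not np.array_equal(disrupted.times, intact.times):
        raise ValueError("waveforms are on different time axes")
    if disrupted.participant_id != intact.participant_id:
        raise ValueError("waveforms belong to different participants")
    return ERPWaveform(
        values=disrupted.values - intact.values,
        times=disrupted.times.copy(),
        n_trials=min(disrupted.n_trials, intact.n_trials),
        participant_id=disrupted.participant_id,
        group=disrupted.group,
        task=disrupted.task,
        sequence_type="disrupted-intact",
        channel=disrupted.channel,
    )


def window_mask(times: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Inclusive window selection in ms, resolved to the sampled time axis.

    Windows are closed at both ends; a sample exactly at an edge (to within
    half a floating-point ULP of the step) is included.
    """
    lo, hi = window_ms
    if hi < lo:
        raise ValueError(f"window end {hi} before start {lo}")
    eps = 1e-9
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    return mask
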