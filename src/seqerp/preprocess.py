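"""Filtering, epoching, baseline correction, artifact rejection, participant
exclusion and condition averaging.

The pipeline order is fixed: filter → epoch → baseline → reject → exclude →
average. Every step is a pure function of its input (rejection only flags
trials; it never alters retained samples), so re-running on identical input
is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import firwin, oaconvolve

from .containers import (ContinuousRecording, EpochSet, ERPWaveform,
                         window_mask)


class EmptyConditionError(ValueError):
    """Raised when a requested condition has no usable trials."""


# ---------------------------------------------------------------------------
# Band-pass filter
# ---------------------------------------------------------------------------

def _transition_bandwidth(freq: float) -> float:
    # min(max(f/4, 2 Hz), f): 0.1 Hz transition at the 0.1 Hz edge (steep
    # enough to suppress 0.01 Hz drift), 10 Hz at the 40 Hz edge.
    return min(max(freq * 0.25, 2.0), freq)


@lru_cache(maxsize=8)
def design_bandpass(sample_rate: float, low_hz: float, high_hz: float
                    ) -> np.ndarray:
    """Hamming windowed sinc FIR band-pass kernel (odd length, linear phase).

    The kernel length follows the Hamming transition-width relation
    Δf ≈ 3.3/N applied to the narrower of the two transition bands.
    """
    if high_hz >= sample_rate / 2.0:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at or above Nyquist "
            f"({sample_rate / 2.0} Hz)")
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    trans = min(_transition_bandwidth(low_hz), _transition_bandwidth(high_hz))
    numtaps = int(np.ceil(3.3 * sample_rate / trans))
    numtaps += (numtaps + 1) % 2  # odd → integer group delay
    return firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                  window="hamming", fs=sample_rate)


def bandpass_filter(signal: np.ndarray, sample_rate: float,
                    low_hz: float = 0.1, high_hz: float = 40.0) -> np.ndarray:
    """Zero-delay band-pass (default 0.1–40 Hz) along the last axis.

    The linear-phase FIR is applied once with its group delay compensated;
    edges are handled by (repeated) signal reflection.
    """
    h = design_bandpass(float(sample_rate), float(low_hz), float(high_hz))
    x = np.asarray(signal, dtype=float)
    pad = len(h) // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect",
                reflect_type="odd")
    y = oaconvolve(xp, h[(None,) * (x.ndim - 1)], mode="valid", axes=-1)
    return y


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(recording: ContinuousRecording,
          window_ms: tuple[float, float] = (-250.0, 1000.0),
          shift_ms: float = 0.0,
          trial_metadata: pd.DataFrame | None = None,
          participant_id: str = "", group: str = "", task: str = "",
          ) -> EpochSet:
    """Cut one epoch per event marker; time 0 = event + ``shift_ms``.

    ``shift_ms`` is 300 for the temporal task (the offset of the shorter
    stimulus), 0 otherwise. Windows are closed at both ends and resolved to
    the nearest sample. Events too close to a recording edge are kept but
    flagged rejected (never silently dropped).
    """
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError("epoch window end must exceed start")
    fs = recording.sample_rate
    step = 1000.0 / fs
    shift_samp = int(np.round(shift_ms / step))
    i_lo = int(np.round(lo / step))
    i_hi = int(np.round(hi / step))
    times = np.arange(i_lo, i_hi + 1) * step
    n_samp = times.size

    events = recording.events["sample"].to_numpy(dtype=int)
    n_trials = events.size
    data = np.zeros((n_trials, n_samp))
    edge_flag = np.zeros(n_trials, dtype=bool)
    for i, ev in enumerate(events):
        start = ev + shift_samp + i_lo
        stop = ev + shift_samp + i_hi  # inclusive
        if start < 0 or stop >= recording.data.size:
            edge_flag[i] = True
            continue
        data[i] = recording.data[start:stop + 1]

    if trial_metadata is not None:
        trials = trial_metadata.reset_index(drop=True).copy()
        if len(trials) != n_trials:
            raise ValueError("trial_metadata rows must match event count")
    else:
        trials = pd.DataFrame({
            "trial": np.arange(1, n_trials + 1),
            "sequence_type": "intact",
            "disruption_position": "none",
            "response_correct": True,
        })
    trials["rejected"] = edge_flag
    if edge_flag.any():
        trials.loc[edge_flag, "rejection_reason"] = "edge"
    return EpochSet(data=data, times=times, sample_rate=fs,
                    participant_id=participant_id, group=group, task=task,
                    trials=trials, channel=recording.channel)


# ---------------------------------------------------------------------------
# Baseline, rejection, exclusion, averaging
# ---------------------------------------------------------------------------

def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] = (-250.0, 0.0)
                     ) -> EpochSet:
    """Subtract each trial's mean over the baseline window (inclusive)."""
    mask = window_mask(epochs.times, window_ms)
    out = epochs.copy()
    out.data -= out.data[:, mask].mean(axis=1, keepdims=True)
    return out


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 100.0,
                     manual_blacklist: Sequence[int] | None = None
                     ) -> EpochSet:
    """Flag trials whose absolute amplitude passes beyond ``threshold_uv``.

    The threshold is a strict inequality (|v| > threshold). The optional
    ``manual_blacklist`` of trial numbers is applied afterwards, modelling
    the manual-inspection half of a semi-automated procedure.
    """
    out = epochs.copy()
    auto = np.abs(out.data).max(axis=1) > threshold_uv
    rejected = out.trials["rejected"].to_numpy(dtype=bool) | auto
    out.trials["rejected"] = rejected
    if manual_blacklist:
        manual = out.trials["trial"].isin(list(manual_blacklist)).to_numpy()
        out.trials["rejected"] = out.trials["rejected"] | manual
    return out


def exclude_low_trial_participants(
        epoch_sets: Iterable[EpochSet], min_trials: int = 10,
        conditions: tuple[str, str] = ("intact", "disrupted"),
        correct_only: bool = False,
) -> tuple[list[EpochSet], pd.DataFrame]:
    """Drop participants with fewer than ``min_trials`` usable trials in
    either condition; return the retained sets and an exclusion report.

    A participant is retained iff *both* conditions have >= min_trials
    non-rejected trials (>= is inclusive: 10 of 10 is kept). The report has
    one row per participant × task with the per-condition counts.
    """
    retained: list[EpochSet] = []
    rows = []
    for es in epoch_sets:
        usable = es.usable_mask(correct_only=correct_only)
        seq = es.trials["sequence_type"].to_numpy()
        counts = {c: int((usable & (seq == c)).sum()) for c in conditions}
        excluded = any(counts[c] < min_trials for c in conditions)
        rows.append({"participant": es.participant_id, "group": es.group,
                     "task": es.task,
                     **{f"n_{c}": counts[c] for c in conditions},
                     "excluded": excluded})
        if not excluded:
            retained.append(es)
    report = pd.DataFrame(rows)
    return retained, report


def average_erp(epochs: EpochSet, correct_only: bool = True,
                conditions: tuple[str, ...] = ("intact", "disrupted")
                ) -> dict[str, ERPWaveform]:
    """Pointwise mean over non-rejected (and, by default, correct) trials,
    separately per sequence type."""
    out: dict[str, ERPWaveform] = {}
    usable = epochs.usable_mask(correct_only=correct_only)
    seq = epochs.trials["sequence_type"].to_numpy()
    for cond in conditions:
        mask = usable & (seq == cond)
        n = int(mask.sum())
        if n == 0:
            raise EmptyConditionError(
                f"participant {epochs.participant_id}, task {epochs.task}: "
                f"no usable trials in condition '{cond}'")
        out[cond] = ERPWaveform(
            values=epochs.data[mask].mean(axis=0), times=epochs.times.copy(),
            n_trials=n, participant_id=epochs.participant_id,
            group=epochs.group, task=epochs.task, sequence_type=cond,
            channel=epochs.channel)
    return out


@dataclass
class PreprocessResult:
    erps: list[ERPWaveform]
    exclusion_report: pd.DataFrame


def preprocess_epoch_sets(epoch_sets: Iterable[EpochSet],
                          baseline_window: tuple[float, float] = (-250.0, 0.0),
                          threshold_uv: float = 100.0,
                          min_trials: int = 10,
                          correct_only: bool = True) -> PreprocessResult:
    """Baseline → reject → exclude → average over a collection of
    already-epoched data (one EpochSet per participant × task)."""
    processed = [reject_artifacts(baseline_correct(es, baseline_window),
                                  threshold_uv)
                 for es in epoch_sets]
    retained, report = exclude_low_trial_participants(processed, min_trials)
    erps: list[ERPWaveform] = []
    for es in retained:
        try:
            erps.extend(average_erp(es, correct_only=correct_only).values())
        except EmptyConditionError as err:
            warnings.warn(str(err))
    return PreprocessResult(erps=erps, exclusion_report=report)
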