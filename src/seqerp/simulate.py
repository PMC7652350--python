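"""Synthetic serial-prediction-task study with known ground truth.

EEG epochs are generated directly at the epoch level (time-locked to the
disrupting stimulus, or the matched position on intact trials): a Gaussian
P3-like bump whose amplitude depends on group × sequence type and whose
center is the participant's true latency plus single-trial jitter, on top
of 1/f ("pink") background noise plus white sensor noise. Behavioral tables
carry Bernoulli yes/no accuracy and, for the visuomotor task, per-stimulus
reaction times following a decreasing power law (linear in log RT) with a
slowing at the disrupting stimulus.

The correctness flag is drawn independently of the EEG signal; the two are
linked downstream only through correct-trial averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (DISRUPTION_POSITIONS, N_STIMULI, SimulationConfig)
from .containers import EpochSet


@dataclass
class GroundTruth:
    """True simulation parameters, one record per participant (and per
    group × task × sequence-type cell for accuracy)."""

    participants: pd.DataFrame  # participant, group, p3 latency/amplitudes, rt slope
    accuracy: pd.DataFrame      # group, task, sequence_type, p_correct


def pink_noise(rng: np.random.Generator, shape: tuple[int, int],
               sample_rate: float, sd: float, exponent: float = 1.0
               ) -> np.ndarray:
    """1/f^alpha noise rows via spectral shaping of white noise.

    The scaling is analytic (Parseval), so the *expected* per-sample SD is
    exactly ``sd``; individual realizations fluctuate around it.
    """
    n_rows, n_samples = shape
    if sd == 0 or n_samples == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= scale
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    # E[sum x^2] per row = 2*sum(s_k^2) over interior bins + s_Nyq^2 (DC zeroed)
    s2 = scale ** 2
    interior = s2[1:-1].sum() if n_samples % 2 == 0 else s2[1:].sum()
    nyq = s2[-1] if n_samples % 2 == 0 else 0.0
    expected_var = (2.0 * interior + nyq) / n_samples
    return out * (sd / np.sqrt(expected_var))


def _participant_table(config: SimulationConfig, rng: np.random.Generator
                       ) -> pd.DataFrame:
    rows = []
    for group in sorted(config.n_per_group):
        n = config.n_per_group[group]
        lat = rng.normal(config.p3_latency_mean[group], config.p3_latency_sd,
                         size=n)
        slope = rng.normal(config.rt_slope_log.get(group, 0.0),
                           config.rt_slope_sd, size=n)
        for i in range(n):
            rows.append({
                "participant": f"{group}{i + 1:02d}",
                "group": group,
                "p3_latency_ms": lat[i],
                "p3_amplitude_disrupted":
                    config.p3_amplitude[(group, "disrupted")],
                "p3_amplitude_intact":
                    config.p3_amplitude[(group, "intact")],
                "rt_slope_log": slope[i],
            })
    return pd.DataFrame(rows)


def _trial_frame(config: SimulationConfig, group: str, task: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial design: balanced disrupted/intact split, disruption position
    uniform over {10, 11}, correctness Bernoulli(accuracy_probs)."""
    n = config.n_trials(task)
    n_disrupted = int(round(config.p_disrupted * n))
    seq = np.array(["disrupted"] * n_disrupted + ["intact"] * (n - n_disrupted))
    rng.shuffle(seq)
    pos = np.where(seq == "disrupted",
                   rng.choice(DISRUPTION_POSITIONS, size=n).astype(object),
                   "none")
    p_correct = np.array([config.accuracy_probs[(group, s)] for s in seq])
    correct = rng.random(n) < p_correct
    return pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "sequence_type": seq,
        "disruption_position": pos,
        "response_correct": correct,
        "rejected": False,
    })


def ground_truth_accuracy(config: SimulationConfig) -> pd.DataFrame:
    rows = [{"group": g, "task": t, "sequence_type": s,
             "p_correct": config.accuracy_probs[(g, s)]}
            for g in sorted(config.n_per_group) for t in config.tasks
            for s in ("intact", "disrupted")]
    return pd.DataFrame(rows)


def simulate_epochs(config: SimulationConfig
                    ) -> tuple[list[EpochSet], GroundTruth]:
    """Generate one EpochSet per participant × task, plus ground truth.

    Each epoch = Gaussian bump (amplitude per group × sequence type, center
    at the participant's true latency + trial jitter) + pink noise + white
    noise, with an occasional square ±150 µV glitch standing in for gross
    artifacts. Trial metadata carries sequence type, disruption position and
    the simulated correctness flag.
    """
    rng = np.random.default_rng(config.seed)
    truth_participants = _participant_table(config, rng)
    lo, hi = config.epoch_window
    step = 1000.0 / config.sample_rate
    times = np.arange(np.round(lo / step), np.round(hi / step) + 1) * step

    epoch_sets: list[EpochSet] = []
    for _, prow in truth_participants.iterrows():
        group = prow["group"]
        for task in config.tasks:
            trials = _trial_frame(config, group, task, rng)
            n = len(trials)
            amp = np.where(trials["sequence_type"] == "disrupted",
                           prow["p3_amplitude_disrupted"],
                           prow["p3_amplitude_intact"])[:, None]
            centers = (prow["p3_latency_ms"]
                       + rng.normal(0.0, config.p3_jitter_sd, size=n))[:, None]
            bump = amp * np.exp(-0.5 * ((times[None, :] - centers)
                                        / config.p3_width) ** 2)
            data = bump
            if config.noise_pink_sd > 0:
                data = data + pink_noise(rng, (n, times.size),
                                         config.sample_rate,
                                         config.noise_pink_sd,
                                         config.noise_pink_exponent)
            if config.noise_white_sd > 0:
                data = data + rng.normal(0.0, config.noise_white_sd,
                                         size=(n, times.size))
            if config.p_artifact > 0:
                hit = rng.random(n) < config.p_artifact
                for i in np.flatnonzero(hit):
                    start = rng.integers(0, times.size - 25)
                    sign = rng.choice([-1.0, 1.0])
                    data[i, start:start + 25] += sign * config.artifact_amplitude_uv
            epoch_sets.append(EpochSet(
                data=data, times=times.copy(), sample_rate=config.sample_rate,
                participant_id=prow["participant"], group=group, task=task,
                trials=trials))
    truth = GroundTruth(participants=truth_participants,
                        accuracy=ground_truth_accuracy(config))
    return epoch_sets, truth


def simulate_behavior(config: SimulationConfig
                      ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the tidy behavioral trial table, plus ground truth.

    Yes/no responses are derived from the simulated correctness flag
    (correct ⇔ 'yes' on disrupted trials, 'no' on intact trials). For the
    visuomotor task, RT at response k (k = 1..12) is
    exp(log(rt_intercept) + slope·k + ε), ε ~ N(0, rt_noise²), with
    ``rt_disruption_cost`` ms added at the disrupting stimulus on disrupted
    trials.
    """
    # Offset stream so behavioral draws are independent of the EEG draws but
    # still fully determined by config.seed.
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    truth_participants = _participant_table(
        config, np.random.default_rng(config.seed))
    rt_cols = [f"rt_{k:02d}" for k in range(1, N_STIMULI + 1)]

    frames = []
    for _, prow in truth_participants.iterrows():
        group = prow["group"]
        for task in config.tasks:
            trials = _trial_frame(config, group, task, rng)
            n = len(trials)
            tab = trials.drop(columns=["rejected"]).copy()
            tab.insert(0, "participant", prow["participant"])
            tab.insert(1, "group", group)
            tab.insert(2, "task", task)
            disrupted = tab["sequence_type"].to_numpy() == "disrupted"
            tab["response"] = np.where(
                disrupted == tab["response_correct"].to_numpy(), "yes", "no")
            tab = tab.rename(columns={"response_correct": "correct"})
            if task == "visuomotor":
                k = np.arange(1, N_STIMULI + 1)[None, :]
                log_rt = (np.log(config.rt_intercept)
                          + prow["rt_slope_log"] * k)
                noise = (rng.normal(0.0, config.rt_noise,
                                    size=(n, N_STIMULI))
                         if config.rt_noise > 0 else 0.0)
                rt = np.exp(np.broadcast_to(log_rt, (n, N_STIMULI)) + noise)
                rt = np.ascontiguousarray(rt)
                pos = tab["disruption_position"].to_numpy()
                for i in np.flatnonzero(disrupted):
                    rt[i, int(pos[i]) - 1] += config.rt_disruption_cost
                tab[rt_cols] = rt
            else:
                tab[rt_cols] = np.nan
            frames.append(tab)
    behavior = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(participants=truth_participants,
                        accuracy=ground_truth_accuracy(config))
    return behavior, truth
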