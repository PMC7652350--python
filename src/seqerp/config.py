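"""Study configuration objects.

`SimulationConfig` fixes the generative model for the synthetic serial
prediction task (SPT) study: two groups of children (DCD and TD) performing
five tasks, with single-channel (Pz) epochs around the sequence-disruption
point and trial-level behavioral responses. Defaults encode the study
conditions: group sizes 24/23, 60 trials per task (72 visuomotor), half of
the trials disrupted at stimulus position 10 or 11, 500 Hz sampling over
−250..1000 ms, and a P3-like positivity on disrupted trials that peaks
~84 ms later in the DCD group.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

GROUPS = ("DCD", "TD")
TASKS = ("control", "spatial", "temporal", "visual", "visuomotor")

#: Responses per visuomotor trial: six repetitions of a two-element sequence.
N_STIMULI = 12
#: The sequence is disrupted at one of these stimulus positions.
DISRUPTION_POSITIONS = (10, 11)


def _default_accuracy() -> dict[tuple[str, str], float]:
    # Poorer discrimination in DCD, worse on disrupted than intact trials,
    # consistent with overall intact/disrupted means of ~.91/.82.
    return {
        ("TD", "intact"): 0.93, ("TD", "disrupted"): 0.88,
        ("DCD", "intact"): 0.88, ("DCD", "disrupted"): 0.76,
    }


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic SPT study.

    Amplitudes are µV, times/latencies ms, rates Hz. ``seed`` is mandatory:
    identical seed + config produce byte-identical outputs.
    """

    seed: int
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"DCD": 24, "TD": 23})
    tasks: tuple[str, ...] = TASKS
    trials_per_task: int = 60
    visuomotor_trials: int = 72
    p_disrupted: float = 0.5
    sample_rate: float = 500.0
    epoch_window: tuple[float, float] = (-250.0, 1000.0)
    # P3 component: Gaussian bump, amplitude per (group, sequence_type).
    p3_amplitude: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("TD", "intact"): 2.0, ("TD", "disrupted"): 10.0,
            ("DCD", "intact"): 2.0, ("DCD", "disrupted"): 10.0,
        })
    p3_latency_mean: dict[str, float] = field(
        default_factory=lambda: {"TD": 700.0, "DCD": 784.0})
    p3_latency_sd: float = 30.0       # between participants
    p3_jitter_sd: float = 40.0        # single-trial latency jitter
    p3_width: float = 80.0            # Gaussian SD of the component
    noise_white_sd: float = 8.0
    noise_pink_sd: float = 12.0
    noise_pink_exponent: float = 1.0  # power ∝ 1/f^alpha
    p_artifact: float = 0.05          # chance a trial carries a ±150 µV glitch
    artifact_amplitude_uv: float = 150.0
    accuracy_probs: dict[tuple[str, str], float] = field(
        default_factory=_default_accuracy)
    # Visuomotor RT learning: log RT = log(intercept) + slope·k + noise.
    rt_intercept: float = 1000.0
    rt_slope_log: dict[str, float] = field(
        default_factory=lambda: {"DCD": -0.098, "TD": -0.075})
    rt_slope_sd: float = 0.02         # between participants
    rt_disruption_cost: float = 150.0
    rt_noise: float = 0.25            # lognormal sigma

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int,)) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        if not 0.0 <= self.p_disrupted <= 1.0:
            raise ValueError("p_disrupted must lie in [0, 1]")
        if not 0.0 <= self.p_artifact <= 1.0:
            raise ValueError("p_artifact must lie in [0, 1]")
        for key, p in self.accuracy_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy_probs[{key}]={p} outside [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = self.epoch_window
        if not (lo < 0.0 < hi):
            raise ValueError("epoch_window must straddle 0 (start < 0 < end)")
        for grp, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"n_per_group[{grp}] must be positive")
        if self.trials_per_task <= 0 or self.visuomotor_trials <= 0:
            raise ValueError("trial counts must be positive")
        for name in ("p3_latency_sd", "p3_jitter_sd", "p3_width",
                     "noise_white_sd", "noise_pink_sd", "rt_noise",
                     "rt_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rt_intercept <= 0:
            raise ValueError("rt_intercept must be positive")
        for grp in self.n_per_group:
            if grp not in self.p3_latency_mean:
                raise ValueError(f"p3_latency_mean missing group {grp}")

    def n_trials(self, task: str) -> int:
        return self.visuomotor_trials if task == "visuomotor" \
            else self.trials_per_task

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run."""

    simulation: SimulationConfig
    out_dir: str = "seqerp_out"
    seed: int | None = None           # defaults to simulation.seed
    # preprocessing
    baseline_window: tuple[float, float] = (-250.0, 0.0)
    rejection_threshold_uv: float = 100.0
    min_trials: int = 10
    correct_only: bool = True
    # cluster statistics
    cluster_alpha: float = 0.05
    n_permutations: int = 2000
    p3_window: tuple[float, float] = (400.0, 1000.0)
    # latency
    latency_fraction: float = 0.5
    latency_window: str | tuple[float, float] = "auto"
    # stage toggles
    run_behavior: bool = True
    run_eeg: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            self.seed = self.simulation.seed

    def to_dict(self) -> dict[str, Any]:
        return _jsonable(dataclasses.asdict(self))


def _jsonable(obj: Any) -> Any:
    """Recursively convert tuple-keyed dicts/tuples into YAML/JSON-safe forms."""
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "|".join(map(str, k))):
                _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _tuple_keys(mapping: Mapping[str, Any]) -> dict:
    return {(tuple(k.split("|")) if "|" in k else k): v
            for k, v in mapping.items()}


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file (tuple keys encoded 'a|b')."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("p3_amplitude", "accuracy_probs"):
        if key in raw:
            raw[key] = _tuple_keys(raw[key])
    for key in ("epoch_window",):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "tasks" in raw:
        raw["tasks"] = tuple(raw["tasks"])
    return SimulationConfig(**raw)


def save_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(dataclasses.asdict(config)), fh,
                       sort_keys=True)
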