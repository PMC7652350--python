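"""End-to-end pipeline: simulate (or load) → preprocess → cluster test per
condition and group → latency/jackknife → behavior, with a machine-readable
JSON summary and human-readable TSV tables.

Every stage logs its parameters and exclusion counts; one global seed
deterministically derives per-stage seeds, so a run is reproducible from
its saved configuration alone.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .cluster import (amplitude_anova, cluster_permutation_test,
                      extract_cluster_mean_amplitude)
from .config import RunConfig
from .containers import ERPWaveform, difference_wave
from .latency import (adjusted_group_test, jackknife_latencies,
                      mean_group_delay)
from .preprocess import preprocess_epoch_sets
from .simulate import simulate_behavior, simulate_epochs

log = logging.getLogger("seqerp")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the global seed."""
    ss = np.random.SeedSequence([master, sum(map(ord, stage))])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _difference_waves(erps: list[ERPWaveform]
                      ) -> dict[tuple[str, str], list[ERPWaveform]]:
    """Group ERPs into (task, group) → list of disrupted−intact waves."""
    by_participant: dict[tuple, dict[str, ERPWaveform]] = defaultdict(dict)
    for erp in erps:
        by_participant[(erp.task, erp.group, erp.participant_id)][
            erp.sequence_type] = erp
    out: dict[tuple[str, str], list[ERPWaveform]] = defaultdict(list)
    for (task, group, _pid), conds in sorted(by_participant.items()):
        if {"intact", "disrupted"} <= set(conds):
            out[(task, group)].append(
                difference_wave(conds["disrupted"], conds["intact"]))
    return out


def _union_window(results: list, p3_window: tuple[float, float],
                  alpha: float = 0.05) -> tuple[float, float]:
    """Measurement window: span of significant clusters clipped to the P3
    window; fallback to the full P3 window when no cluster is significant."""
    lo, hi = np.inf, -np.inf
    for res in results:
        for c in res.significant(alpha):
            lo = min(lo, c.start_ms)
            hi = max(hi, c.end_ms)
    lo = max(lo, p3_window[0])
    hi = min(hi, p3_window[1])
    if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
        return tuple(p3_window)
    return (float(lo), float(hi))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and optionally write) the
    report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "stages": {}}

    sim = config.simulation
    # ----- EEG chain -------------------------------------------------------
    if config.run_eeg:
        try:
            epoch_sets, truth = simulate_epochs(sim)
        except Exception as err:  # noqa: BLE001
            raise StageError("simulate", str(err)) from err
        log.info("simulate: %d epoch sets, seed=%d", len(epoch_sets), sim.seed)
        try:
            pre = preprocess_epoch_sets(
                epoch_sets, baseline_window=config.baseline_window,
                threshold_uv=config.rejection_threshold_uv,
                min_trials=config.min_trials,
                correct_only=config.correct_only)
        except Exception as err:  # noqa: BLE001
            raise StageError("preprocess", str(err)) from err
        n_excluded = int(pre.exclusion_report["excluded"].sum())
        log.info("preprocess: %d ERPs, %d participant×task exclusions",
                 len(pre.erps), n_excluded)
        summary["stages"]["preprocess"] = {
            "n_erps": len(pre.erps),
            "n_excluded_participant_tasks": n_excluded,
            "threshold_uv": config.rejection_threshold_uv,
            "min_trials": config.min_trials,
        }
        pre.exclusion_report.to_csv(out_dir / "exclusions.tsv", sep="\t",
                                    index=False)

        diffs = _difference_waves(pre.erps)
        cluster_results: dict[tuple[str, str], object] = {}
        cluster_rows = []
        for (task, group), waves in sorted(diffs.items()):
            arr = np.vstack([w.values for w in waves])
            times = waves[0].times
            seed = _stage_seed(config.seed, f"cluster:{task}:{group}")
            try:
                res = cluster_permutation_test(
                    arr, times, cluster_alpha=config.cluster_alpha,
                    n_permutations=config.n_permutations, seed=seed)
            except Exception as err:  # noqa: BLE001
                raise StageError("cluster-test",
                                 f"{task}/{group}: {err}") from err
            cluster_results[(task, group)] = res
            for c in res.clusters:
                cluster_rows.append({
                    "condition": task, "group": group,
                    "start_ms": c.start_ms, "end_ms": c.end_ms,
                    "mass": c.mass, "p": c.p,
                    "n_participants": arr.shape[0],
                    "method": res.method})
        clusters_df = pd.DataFrame(cluster_rows)
        clusters_df.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        summary["stages"]["cluster"] = {
            "n_permutations": config.n_permutations,
            "cluster_alpha": config.cluster_alpha,
            "clusters": cluster_rows,
        }

        # mean amplitudes over the P3 window + Condition×Group ANOVA
        all_diffs = [w for waves in diffs.values() for w in waves]
        amp_cells = extract_cluster_mean_amplitude(all_diffs,
                                                   config.p3_window)
        amp_cells.to_csv(out_dir / "amplitudes.tsv", sep="\t", index=False)
        try:
            amp_table = amplitude_anova(amp_cells)
            summary["stages"]["amplitude_anova"] = {
                r["Source"]: {"F": float(r["F"]),
                              "df1": int(r["DF"]) if "DF" in r else None,
                              "p": float(r["p_unc"])}
                for _, r in amp_table.iterrows()
                if r["Source"] != "Residual" and np.isfinite(r["F"])}
        except ValueError as err:
            log.warning("amplitude ANOVA skipped: %s", err)
            summary["stages"]["amplitude_anova"] = {"skipped": str(err)}

        # latency / jackknife per condition
        latency_rows = []
        tasks = sorted({t for (t, _g) in diffs})
        groups = sorted({g for (_t, g) in diffs})
        for task in tasks:
            if config.latency_window == "auto":
                window = _union_window(
                    [cluster_results[(task, g)] for g in groups
                     if (task, g) in cluster_results], config.p3_window)
            else:
                window = tuple(config.latency_window)
            results = {}
            for group in groups:
                waves = diffs.get((task, group), [])
                if len(waves) < 3:
                    continue
                arr = np.vstack([w.values for w in waves])
                try:
                    results[group] = jackknife_latencies(
                        arr, waves[0].times, window,
                        fraction=config.latency_fraction,
                        group=group, condition=task)
                except Exception as err:  # noqa: BLE001
                    raise StageError("latency",
                                     f"{task}/{group}: {err}") from err
            test = None
            if len(results) == 2:
                g_a, g_b = groups
                test = adjusted_group_test(
                    results[g_a].jackknife_replicates,
                    results[g_b].jackknife_replicates)
            for group, lat in results.items():
                latency_rows.append({
                    "group": group, "condition": task,
                    "latency_ms": lat.latency_ms,
                    "replicate_sd": lat.replicate_sd,
                    "N": lat.N,
                    "window_start_ms": window[0],
                    "window_end_ms": window[1],
                    "F_adjusted": test.F_adjusted if test else np.nan,
                    "p": test.p if test else np.nan,
                    "N_adjustment": test.N if test else np.nan,
                })
        latency_df = pd.DataFrame(latency_rows)
        latency_df.to_csv(out_dir / "latency_table.tsv", sep="\t",
                          index=False)
        summary["stages"]["latency"] = {
            "fraction": config.latency_fraction,
            "table": latency_rows}
        if len(latency_df) and latency_df["group"].nunique() == 2:
            g_a, g_b = sorted(latency_df["group"].unique())
            try:
                summary["stages"]["latency"]["mean_group_delay_ms"] = \
                    mean_group_delay(latency_df, tasks, group_a=g_a,
                                     group_b=g_b)
            except KeyError as err:
                log.warning("mean group delay skipped: %s", err)

    # ----- behavioral chain ------------------------------------------------
    if config.run_behavior:
        try:
            trials, truth_b = simulate_behavior(sim)
        except Exception as err:  # noqa: BLE001
            raise StageError("simulate-behavior", str(err)) from err
        summary["stages"]["behavior"] = _run_behavior_stage(trials, out_dir,
                                                            config)

    path = out_dir / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    log.info("wrote %s", path)
    return summary


def _run_behavior_stage(trials: pd.DataFrame, out_dir: Path,
                        config: RunConfig) -> dict:
    """Accuracy + RT-learning analyses; skips gracefully on empty input."""
    if trials is None or len(trials) == 0:
        log.warning("behavior stage skipped: empty trial table")
        return {"skipped": "empty trial table"}
    out: dict = {}
    cells = beh.accuracy_table(trials, min_responses=config.min_trials)
    cells.to_csv(out_dir / "accuracy_cells.tsv", sep="\t", index=False)
    out["accuracy_cell_means"] = {
        seq: float(sub["prop_correct"].mean())
        for seq, sub in cells.groupby("sequence_type", observed=True)}
    try:
        anova = beh.accuracy_anova(cells)
        out["accuracy_anova"] = {
            r["Source"]: {"F": float(r["F"]), "p": float(r["p_unc"])}
            for _, r in anova.iterrows()
            if r["Source"] != "Residual" and np.isfinite(r["F"])}
    except ValueError as err:
        log.warning("accuracy ANOVA skipped: %s", err)
    posthoc = beh.posthoc_group_tests(cells)
    pd.DataFrame([vars(p) for p in posthoc]).to_csv(
        out_dir / "posthoc.tsv", sep="\t", index=False)
    out["posthoc_significant"] = [
        f"{p.condition}/{p.sequence_type}" for p in posthoc if p.significant]

    if "visuomotor" in set(trials["task"]):
        slopes = beh.learning_slopes(trials)
        slopes.slopes.to_csv(out_dir / "slopes.tsv", sep="\t", index=False)
        out["learning_slopes"] = {
            "group_means": slopes.group_means, "t": slopes.t,
            "df": slopes.df, "p": slopes.p}
        rt = beh.disruption_rt_test(trials)
        out["disruption_rt"] = {
            r["Source"]: {"F": float(r["F"]), "p": float(r["p_unc"]),
                          "ng2": float(r["ng2"]) if np.isfinite(r["ng2"])
                          else None}
            for _, r in rt.anova.iterrows() if np.isfinite(r["F"])}
        out["first_response_rt"] = rt.first_response
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
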