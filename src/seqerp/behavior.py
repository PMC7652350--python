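"""Behavioral accuracy analysis and visuomotor RT-learning analysis.

Accuracy: proportion correct per participant × task × sequence type, a
SequenceType × Condition × Group ANOVA on those cell proportions (Type III
sums of squares on the pooled cell table, matching the reported df
structure of the design), and per-condition post-hoc group t-tests at
α = .01 with Cohen's D.

RT learning: for the visuomotor task, an OLS line is fitted per participant
to log median RT over response indices 1–9 (per-index medians over trials,
intact and disrupted pooled), and the slopes are compared between groups
with a Welch t-test. The slowing at the disrupting stimulus is tested with
a SequenceType × Group mixed ANOVA (generalized eta squared) on RTs at
positions 10/11, together with a Welch t-test on first-response median RTs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DISRUPTION_POSITIONS, N_STIMULI

T_SENTINEL = 1e6


def _check_required(table: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")


def exclude_low_response_participants(trials: pd.DataFrame,
                                      min_responses: int = 10
                                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per task, drop participants with fewer than ``min_responses``
    responses in either sequence type; mirrors the EEG <10-trial rule."""
    _check_required(trials, ("participant", "task", "sequence_type"))
    counts = (trials.groupby(["task", "participant", "sequence_type"],
                             observed=True)
              .size().unstack("sequence_type", fill_value=0))
    for cond in ("intact", "disrupted"):
        if cond not in counts.columns:
            counts[cond] = 0
    counts["excluded"] = ((counts["intact"] < min_responses)
                          | (counts["disrupted"] < min_responses))
    report = counts.reset_index().rename(
        columns={"intact": "n_intact", "disrupted": "n_disrupted"})
    bad = set(map(tuple, report.loc[report["excluded"],
                                    ["task", "participant"]].to_numpy()))
    keep = ~trials.set_index(["task", "participant"]).index.isin(bad)
    return trials.loc[keep].reset_index(drop=True), report


def accuracy_table(trials: pd.DataFrame, min_responses: int = 10
                   ) -> pd.DataFrame:
    """Proportion correct per participant × task × sequence type.

    Participants failing the ≥``min_responses``-per-condition rule for a
    task are excluded from that task's cells first.
    """
    _check_required(trials, ("participant", "group", "task", "sequence_type",
                             "correct"))
    kept, _report = exclude_low_response_participants(trials, min_responses)
    cells = (kept.groupby(["participant", "group", "task", "sequence_type"],
                          observed=True)
             .agg(n_trials=("correct", "size"),
                  prop_correct=("correct", "mean"))
             .reset_index())
    return cells


def accuracy_anova(cells: pd.DataFrame) -> pd.DataFrame:
    """SequenceType × Condition × Group ANOVA on cell proportions.

    Fitted as crossed fixed factors on the pooled participant × task ×
    sequence-type cell table with Type III sums of squares. Unbalanced or
    empty cells are reported via the ``empty_cells`` attribute.
    """
    import pingouin as pg

    _check_required(cells, ("group", "task", "sequence_type", "prop_correct"))
    for col in ("sequence_type", "task", "group"):
        if cells[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    counts = cells.groupby(["task", "group", "sequence_type"],
                           observed=True).size()
    full = pd.MultiIndex.from_product([cells["task"].unique(),
                                       cells["group"].unique(),
                                       cells["sequence_type"].unique()])
    empty = [idx for idx in full if idx not in counts.index]
    data = cells.rename(columns={"task": "condition"})
    from .cluster import zero_effect_f

    table = pg.anova(data=data, dv="prop_correct",
                     between=["sequence_type", "condition", "group"],
                     ss_type=3)
    table = zero_effect_f(table)
    table.attrs["empty_cells"] = empty
    return table


@dataclass
class PosthocResult:
    condition: str
    sequence_type: str
    t: float
    df: float
    p: float
    cohens_d: float
    significant: bool
    alpha: float


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's D with the pooled standard deviation."""
    n1, n2 = len(a), len(b)
    sp2 = (((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1))
           / (n1 + n2 - 2))
    if sp2 == 0.0:
        return 0.0 if np.mean(a) == np.mean(b) else np.inf
    return float((np.mean(a) - np.mean(b)) / np.sqrt(sp2))


def posthoc_group_tests(cells: pd.DataFrame, alpha: float = 0.01,
                        group_a: str = "DCD", group_b: str = "TD",
                        equal_var: bool = True) -> list[PosthocResult]:
    """Two-sample t (pooled-variance by default) with Cohen's D per
    condition × sequence type, flagged at ``alpha``."""
    _check_required(cells, ("group", "task", "sequence_type", "prop_correct"))
    results = []
    for (task, seq), sub in cells.groupby(["task", "sequence_type"],
                                          observed=True, sort=True):
        a = sub.loc[sub["group"] == group_a, "prop_correct"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "prop_correct"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 participants per group in cell "
                             f"({task}, {seq})")
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            if np.mean(a) == np.mean(b):
                t_val, p_val, d = 0.0, 1.0, 0.0
            else:
                warnings.warn(f"zero variance in cell ({task}, {seq}): "
                              "t set to sentinel")
                t_val = np.sign(np.mean(a) - np.mean(b)) * T_SENTINEL
                p_val, d = 0.0, np.inf
            df = len(a) + len(b) - 2
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            t_val, p_val = float(res.statistic), float(res.pvalue)
            df = float(res.df)
            d = cohens_d(a, b)
        results.append(PosthocResult(condition=task, sequence_type=seq,
                                     t=t_val, df=df, p=p_val, cohens_d=d,
                                     significant=p_val < alpha, alpha=alpha))
    return results


# ---------------------------------------------------------------------------
# Visuomotor RT learning
# ---------------------------------------------------------------------------

def _rt_long(trials: pd.DataFrame) -> pd.DataFrame:
    rt_cols = [f"rt_{k:02d}" for k in range(1, N_STIMULI + 1)]
    _check_required(trials, ("participant", "group", "task", "trial",
                             "sequence_type") + tuple(rt_cols))
    vm = trials.loc[trials["task"] == "visuomotor"]
    long = vm.melt(id_vars=["participant", "group", "trial", "sequence_type",
                            "disruption_position"],
                   value_vars=rt_cols, var_name="position",
                   value_name="rt_ms")
    long["position"] = long["position"].str.slice(3).astype(int)
    return long.dropna(subset=["rt_ms"])


@dataclass
class SlopeResult:
    slopes: pd.DataFrame          # participant, group, slope
    group_means: dict[str, float]
    t: float
    df: float
    p: float
    n_responses: int
    n_excluded_trials: int
    fit_note: str = ("OLS of log(median RT per response index) on index 1..9,"
                     " intact and disrupted trials pooled")


def learning_slopes(trials: pd.DataFrame, n_responses: int = 9,
                    group_a: str = "DCD", group_b: str = "TD") -> SlopeResult:
    """Per-participant log-RT learning slope and the between-group t-test.

    For each participant, the median RT per response index (1..n_responses,
    over all visuomotor trials, intact and disrupted pooled) is
    log-transformed and regressed on the index; the per-participant slopes
    are compared between groups with a Welch t-test. Trials containing a
    non-positive RT in the fitted range are excluded (logged in the result).
    """
    long = _rt_long(trials)
    long = long.loc[long["position"] <= n_responses]
    bad_trials = long.loc[long["rt_ms"] <= 0, ["participant", "trial"]]
    n_excluded = 0
    if len(bad_trials):
        bad = set(map(tuple, bad_trials.to_numpy()))
        n_excluded = len(bad)
        warnings.warn(f"excluding {n_excluded} trial(s) with non-positive RT")
        keep = ~long.set_index(["participant", "trial"]).index.isin(bad)
        long = long.loc[keep]

    med = (long.groupby(["participant", "group", "position"], observed=True)
           ["rt_ms"].median().reset_index())
    rows = []
    for (pid, grp), sub in med.groupby(["participant", "group"],
                                       observed=True):
        if sub["position"].nunique() < n_responses:
            warnings.warn(f"participant {pid}: fewer than {n_responses} "
                          "response indices; skipped")
            continue
        slope = np.polyfit(sub["position"], np.log(sub["rt_ms"]), 1)[0]
        rows.append({"participant": pid, "group": grp,
                     "slope": float(slope)})
    slopes = pd.DataFrame(rows)
    a = slopes.loc[slopes["group"] == group_a, "slope"].to_numpy()
    b = slopes.loc[slopes["group"] == group_b, "slope"].to_numpy()
    if len(a) >= 2 and len(b) >= 2 and (np.var(a) + np.var(b)) > 0:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_val, p_val, df = float(res.statistic), float(res.pvalue), \
            float(res.df)
    else:
        t_val, p_val, df = np.nan, np.nan, np.nan
    return SlopeResult(
        slopes=slopes,
        group_means={group_a: float(a.mean()) if len(a) else np.nan,
                     group_b: float(b.mean()) if len(b) else np.nan},
        t=t_val, df=df, p=p_val, n_responses=n_responses,
        n_excluded_trials=n_excluded)


@dataclass
class DisruptionRTResult:
    anova: pd.DataFrame              # mixed ANOVA with ng2
    cell_means: pd.DataFrame         # participant, group, sequence_type, rt
    first_response: dict             # Welch t on first-response median RTs


def disruption_rt_test(trials: pd.DataFrame) -> DisruptionRTResult:
    """RT slowing at the disrupting stimulus: SequenceType × Group mixed
    ANOVA with generalized eta squared, plus the first-response median-RT
    group comparison.

    Disrupted trials contribute the RT at their disruption position;
    intact trials contribute the matched positions (10/11), weighted per
    participant by that participant's disrupted-position counts so the two
    sequence types are compared at identical positions.
    """
    import pingouin as pg

    long = _rt_long(trials)
    rows = []
    for (pid, grp), sub in long.groupby(["participant", "group"],
                                        observed=True):
        dis = sub.loc[(sub["sequence_type"] == "disrupted")
                      & (sub["disruption_position"].astype(str)
                         == sub["position"].astype(str))]
        weights = dis["position"].value_counts()
        intact_means, dis_means, w_sum = [], [], 0.0
        for pos in DISRUPTION_POSITIONS:
            w = float(weights.get(pos, 0))
            if w == 0:
                continue
            int_pos = sub.loc[(sub["sequence_type"] == "intact")
                              & (sub["position"] == pos), "rt_ms"]
            dis_pos = dis.loc[dis["position"] == pos, "rt_ms"]
            if int_pos.empty:
                continue
            intact_means.append(w * int_pos.mean())
            dis_means.append(w * dis_pos.mean())
            w_sum += w
        if w_sum == 0:
            warnings.warn(f"participant {pid}: no matched disrupted/intact "
                          "positions; skipped")
            continue
        rows.append({"participant": pid, "group": grp,
                     "sequence_type": "intact",
                     "rt_ms": sum(intact_means) / w_sum})
        rows.append({"participant": pid, "group": grp,
                     "sequence_type": "disrupted",
                     "rt_ms": sum(dis_means) / w_sum})
    cell_means = pd.DataFrame(rows)
    if cell_means.empty:
        raise ValueError("no participants with matched disrupted/intact "
                         "positions")
    anova = pg.mixed_anova(data=cell_means, dv="rt_ms",
                           within="sequence_type", subject="participant",
                           between="group", effsize="ng2")
    # degenerate zero-variance designs: zero effect SS ⇒ F = 0; a real
    # effect against a zero error term ⇒ large finite sentinel
    zero = anova["SS"].abs() <= 1e-9
    bad_f = ~np.isfinite(anova["F"]) | (anova["F"] < 0)
    anova.loc[zero, ["F", "p_unc", "ng2"]] = [0.0, 1.0, 0.0]
    anova.loc[~zero & bad_f, ["F", "p_unc"]] = [T_SENTINEL, 0.0]

    first = (long.loc[long["position"] == 1]
             .groupby(["participant", "group"], observed=True)["rt_ms"]
             .median().reset_index())
    groups = sorted(first["group"].unique())
    fr: dict = {"groups": groups}
    if len(groups) == 2:
        a = first.loc[first["group"] == groups[0], "rt_ms"].to_numpy()
        b = first.loc[first["group"] == groups[1], "rt_ms"].to_numpy()
        res = stats.ttest_ind(a, b, equal_var=False)
        fr.update(t=float(res.statistic), df=float(res.df),
                  p=float(res.pvalue),
                  medians={groups[0]: float(np.median(a)),
                           groups[1]: float(np.median(b))})
    return DisruptionRTResult(anova=anova, cell_means=cell_means,
                              first_response=fr)
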