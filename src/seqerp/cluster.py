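"""Paired cluster-based permutation test over time at a single electrode,
plus cluster-window mean amplitudes and their Condition × Group ANOVA.

The test operates on per-participant difference waveforms (disrupted −
intact). Clusters are maximal runs of contiguous timepoints where the
paired t-statistic exceeds the two-sided forming criterion, with all
samples in a run sharing the sign of t; the cluster statistic is the mass
(sum of t-values). The null distribution is the maximum |cluster mass|
under random per-participant sign flips of the difference waves, switching
automatically to exhaustive enumeration of all 2^n sign patterns when that
is no larger than the requested permutation count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ERPWaveform, window_mask

#: Finite stand-in for an infinite t arising from zero variance.
T_SENTINEL = 1e6


def _t_from_signs(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t-series for each row of sign patterns.

    ``diffs`` is (n, T), ``signs`` is (P, n) of ±1. Exploits the fact that
    per-timepoint sums of squares are invariant under sign flips, so only
    the flipped means need a matrix product.
    """
    n = diffs.shape[0]
    sumsq = np.einsum("it,it->t", diffs, diffs)  # (T,)
    mean = (signs @ diffs) / n                   # (P, T)
    var = (sumsq[None, :] - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    zero_var = var <= (np.abs(sumsq[None, :]) + 1.0) * 1e-15
    t = np.where(zero_var & (mean == 0.0), 0.0, t)
    t = np.where(zero_var & (mean != 0.0), np.sign(mean) * T_SENTINEL, t)
    return t


def pointwise_paired_t(erps_a: np.ndarray, erps_b: np.ndarray | None = None
                       ) -> np.ndarray:
    """Paired t at every timepoint on A − B differences.

    ``erps_a`` (and ``erps_b`` if given) are (n_participants, T). Passing a
    single array treats it as the differences directly. Zero-variance
    timepoints with a nonzero mean produce a large finite sentinel
    (±1e6) with a warning.
    """
    diffs = np.atleast_2d(np.asarray(erps_a, dtype=float))
    if erps_b is not None:
        b = np.atleast_2d(np.asarray(erps_b, dtype=float))
        if b.shape != diffs.shape:
            raise ValueError("A and B must be matched (same participants "
                             "and time axis)")
        diffs = diffs - b
    if diffs.shape[0] < 3:
        raise ValueError("need at least 3 participants for a paired t")
    t = _t_from_signs(diffs, np.ones((1, diffs.shape[0])))[0]
    if np.any(np.abs(t) >= T_SENTINEL):
        warnings.warn("zero-variance timepoints with nonzero mean: t set to "
                      "a finite sentinel (±1e6)")
    return t


def _run_bounds(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and stop (exclusive) indices of True runs."""
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    return np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)


def _max_cluster_masses(t: np.ndarray, threshold: float) -> np.ndarray:
    """Maximum |cluster mass| per row of a (P, T) t-matrix, vectorized.

    Positive and negative clusters are formed separately (a run never mixes
    signs); the returned statistic is the largest absolute mass in the row,
    0.0 when the row has no suprathreshold samples.
    """
    t = np.atleast_2d(t)
    P, T = t.shape
    out = np.zeros(P)
    for sign in (1.0, -1.0):
        mask = (sign * t) > threshold
        vals = np.where(mask, sign * t, 0.0)
        cs = np.cumsum(vals, axis=1)
        pad = np.zeros((P, 1), dtype=np.int8)
        d = np.diff(np.concatenate([pad, mask.astype(np.int8), pad], axis=1),
                    axis=1)
        rows, starts = np.nonzero(d == 1)
        rows2, stops = np.nonzero(d == -1)  # same rows, same order
        if rows.size == 0:
            continue
        masses = cs[rows2, stops - 1] - np.where(starts > 0,
                                                 cs[rows, starts - 1], 0.0)
        best = np.zeros(P)
        np.maximum.at(best, rows, masses)
        out = np.maximum(out, best)
    return out


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int          # inclusive
    mass: float           # sum of t-values (signed)
    p: float


@dataclass
class ClusterTestResult:
    t_series: np.ndarray
    times: np.ndarray
    clusters: list[Cluster]
    cluster_alpha: float
    t_threshold: float
    n_permutations: int
    method: str           # 'exhaustive' or 'montecarlo'
    seed: int | None
    tail: str = "two-sided"
    assumptions: dict = field(default_factory=lambda: {
        "cluster_forming_alpha_assumed": True,
        "n_permutations_assumed": True,
    })

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self) -> dict:
        return {
            "clusters": [{"start_ms": c.start_ms, "end_ms": c.end_ms,
                          "mass": c.mass, "p": c.p} for c in self.clusters],
            "cluster_alpha": self.cluster_alpha,
            "t_threshold": self.t_threshold,
            "n_permutations": self.n_permutations,
            "method": self.method, "seed": self.seed, "tail": self.tail,
            "assumptions": self.assumptions,
        }


def _observed_clusters(t: np.ndarray, times: np.ndarray, threshold: float
                       ) -> list[Cluster]:
    clusters: list[Cluster] = []
    for sign in (1.0, -1.0):
        starts, stops = _run_bounds((sign * t) > threshold)
        for a, b in zip(starts, stops):
            clusters.append(Cluster(
                start_ms=float(times[a]), end_ms=float(times[b - 1]),
                start_idx=int(a), end_idx=int(b - 1),
                mass=float(t[a:b].sum()), p=np.nan))
    clusters.sort(key=lambda c: c.start_idx)
    return clusters


def cluster_permutation_test(difference_waveforms: np.ndarray,
                             times: np.ndarray | None = None,
                             cluster_alpha: float = 0.05,
                             n_permutations: int = 2000,
                             seed: int | None = None,
                             method: str = "auto") -> ClusterTestResult:
    """Paired (one-sample on differences) cluster permutation test.

    ``difference_waveforms`` is (n_participants, T). The forming threshold
    is the two-sided t criterion at ``cluster_alpha`` with n−1 df. p-values
    use the +1 Monte-Carlo correction, p = (1 + #{null ≥ |mass|}) /
    (1 + n_permutations); with exhaustive enumeration (2^n ≤ n_permutations,
    or ``method='exhaustive'``) p = #{null ≥ |mass|} / 2^n over all sign
    patterns, which always include the identity.
    """
    diffs = np.atleast_2d(np.asarray(difference_waveforms, dtype=float))
    n, T = diffs.shape
    if times is None:
        times = np.arange(T, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size != T:
        raise ValueError("times length must match waveform length")
    if n < 3:
        raise ValueError("need at least 3 participants")
    if n < 5:
        warnings.warn("fewer than 5 participants: permutation resolution "
                      "is very coarse")

    threshold = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_obs = pointwise_paired_t(diffs)
    clusters = _observed_clusters(t_obs, times, threshold)

    exhaustive = method == "exhaustive" or (method == "auto"
                                            and 2 ** n <= n_permutations)
    if exhaustive:
        patterns = np.array(
            [[1.0 if (i >> j) & 1 else -1.0 for j in range(n)]
             for i in range(2 ** n)])
        n_eff = 2 ** n
    else:
        rng = np.random.default_rng(seed)
        patterns = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        n_eff = n_permutations

    if clusters:
        # Evaluate the null in manageable blocks to bound memory.
        null_max = np.empty(n_eff)
        block = max(1, int(2e7 // max(T * n, 1)))
        for i in range(0, n_eff, block):
            t_null = _t_from_signs(diffs, patterns[i:i + block])
            null_max[i:i + block] = _max_cluster_masses(t_null, threshold)
        for c in clusters:
            exceed = int((null_max >= abs(c.mass)).sum())
            if exhaustive:
                c.p = exceed / n_eff
            else:
                c.p = (1 + exceed) / (1 + n_eff)

    return ClusterTestResult(
        t_series=t_obs, times=times, clusters=clusters,
        cluster_alpha=cluster_alpha, t_threshold=threshold,
        n_permutations=n_eff, method="exhaustive" if exhaustive
        else "montecarlo", seed=seed)


# ---------------------------------------------------------------------------
# Cluster-window mean amplitudes and their ANOVA
# ---------------------------------------------------------------------------

def extract_cluster_mean_amplitude(difference_waves: list[ERPWaveform],
                                   window_ms: tuple[float, float]
                                   ) -> pd.DataFrame:
    """Mean (disrupted − intact) amplitude over ``window_ms`` per participant.

    Returns one row per waveform with columns participant, group, condition,
    window_start_ms, window_end_ms, amplitude_uv.
    """
    rows = []
    for wave in difference_waves:
        mask = window_mask(wave.times, window_ms)
        rows.append({
            "participant": wave.participant_id, "group": wave.group,
            "condition": wave.task,
            "window_start_ms": float(window_ms[0]),
            "window_end_ms": float(window_ms[1]),
            "amplitude_uv": float(wave.values[mask].mean()),
        })
    return pd.DataFrame(rows)


def amplitude_anova(cells: pd.DataFrame) -> pd.DataFrame:
    """Condition × Group ANOVA (Type III) on per-participant difference-score
    mean amplitudes. Empty cells are reported in an ``empty_cells`` attribute
    on the returned table, never silently dropped."""
    import pingouin as pg

    for col in ("condition", "group", "amplitude_uv"):
        if col not in cells.columns:
            raise ValueError(f"cells table missing column {col!r}")
    counts = cells.groupby(["condition", "group"], observed=True).size()
    full = pd.MultiIndex.from_product(
        [cells["condition"].unique(), cells["group"].unique()])
    empty = [idx for idx in full if idx not in counts.index]
    if cells["condition"].nunique() < 2 or cells["group"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    table = pg.anova(data=cells, dv="amplitude_uv",
                     between=["condition", "group"], ss_type=3)
    table = zero_effect_f(table)
    table.attrs["empty_cells"] = empty
    return table


def zero_effect_f(table: pd.DataFrame) -> pd.DataFrame:
    """A zero effect sum of squares means F = 0 (p = 1), even when the
    residual is also zero and the ratio is numerically indeterminate."""
    table = table.copy()
    zero = (table["Source"] != "Residual") & (table["SS"].abs() <= 1e-12)
    table.loc[zero, "F"] = 0.0
    if "p_unc" in table.columns:
        table.loc[zero, "p_unc"] = 1.0
    return table
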