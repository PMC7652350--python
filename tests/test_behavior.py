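"""Behavioral accuracy cells/ANOVA/post-hocs and RT-learning analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqerp import (SimulationConfig, accuracy_anova, accuracy_table,
                    disruption_rt_test, learning_slopes, posthoc_group_tests,
                    simulate_behavior)
from seqerp.behavior import cohens_d, exclude_low_response_participants

RT_COLS = [f"rt_{k:02d}" for k in range(1, 13)]


def behavior_rows(pid, group, task, n_intact, n_disrupted, correct=True,
                  rts=None):
    rows = []
    for i in range(n_intact + n_disrupted):
        seq = "intact" if i < n_intact else "disrupted"
        row = {"participant": pid, "group": group, "task": task,
               "trial": i + 1, "sequence_type": seq,
               "disruption_position": "none" if seq == "intact"
               else (10 if i % 2 else 11),
               "response": "no" if (seq == "intact") == bool(correct)
               else "yes",
               "correct": bool(correct)}
        if rts is not None:
            row.update({c: r for c, r in zip(RT_COLS, rts)})
        rows.append(row)
    return rows


class TestAccuracyTable:
    def test_proportion_is_fraction_correct(self):
        # 20 disrupted trials with 15 correct → 0.75 in that cell
        table = pd.DataFrame(behavior_rows("TD01", "TD", "visual", 10, 20))
        disrupted_idx = table.index[table["sequence_type"] == "disrupted"]
        table.loc[disrupted_idx[:5], "correct"] = False
        cells = accuracy_table(table, min_responses=10).set_index(
            "sequence_type")
        assert cells.loc["disrupted", "prop_correct"] == pytest.approx(0.75)
        assert cells.loc["disrupted", "n_trials"] == 20
        assert cells.loc["intact", "prop_correct"] == 1.0

    def test_all_correct_gives_one_everywhere(self):
        cfg = SimulationConfig(
            seed=0, tasks=("visual", "spatial"), n_per_group={"TD": 3,
                                                              "DCD": 3},
            trials_per_task=24,
            accuracy_probs={(g, s): 1.0 for g in ("DCD", "TD")
                            for s in ("intact", "disrupted")})
        trials, _ = simulate_behavior(cfg)
        cells = accuracy_table(trials)
        assert (cells["prop_correct"] == 1.0).all()

    def test_trial_order_invariance(self, rng):
        cfg = SimulationConfig(seed=4, tasks=("visual",),
                               n_per_group={"TD": 4}, trials_per_task=30)
        trials, _ = simulate_behavior(cfg)
        shuffled = trials.sample(frac=1.0, random_state=1)
        a = accuracy_table(trials).sort_values(
            ["participant", "sequence_type"]).reset_index(drop=True)
        b = accuracy_table(shuffled).sort_values(
            ["participant", "sequence_type"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_low_response_participants_dropped(self):
        rows = behavior_rows("A", "TD", "visual", 10, 10)
        rows += behavior_rows("B", "TD", "visual", 9, 30)
        kept, report = exclude_low_response_participants(
            pd.DataFrame(rows), min_responses=10)
        assert set(kept["participant"]) == {"A"}
        assert report.set_index("participant")["excluded"].to_dict() == \
            {"A": False, "B": True}

    def test_binomial_convergence_to_programmed_probability(self):
        cfg = SimulationConfig(
            seed=11, tasks=("visual",), n_per_group={"TD": 40},
            trials_per_task=60,
            accuracy_probs={("TD", "intact"): 0.8, ("TD", "disrupted"): 0.8})
        trials, _ = simulate_behavior(cfg)
        cells = accuracy_table(trials)
        grand_n = cells["n_trials"].sum()
        half_ci = 2.576 * np.sqrt(0.8 * 0.2 / grand_n)
        assert abs(cells["prop_correct"].mean() - 0.8) < half_ci + 0.01


class TestAccuracyAnova:
    def _cells(self, gap_disrupted=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, base in (("TD", 0.9), ("DCD", 0.9)):
            for task in ("visual", "spatial"):
                for i in range(6):
                    for seq in ("intact", "disrupted"):
                        p = base + rng.normal(0, noise)
                        if grp == "DCD" and seq == "disrupted":
                            p -= gap_disrupted
                        rows.append({"participant": f"{grp}{i}",
                                     "group": grp, "task": task,
                                     "sequence_type": seq, "n_trials": 30,
                                     "prop_correct": p})
        return pd.DataFrame(rows)

    def test_identical_proportions_give_zero_f(self):
        table = accuracy_anova(self._cells())
        effects = table[table["Source"] != "Residual"]
        assert (effects["F"] == 0.0).all()

    def test_group_gap_in_disrupted_cells_drives_interaction(self):
        table = accuracy_anova(self._cells(gap_disrupted=0.2,
                                           noise=0.01)).set_index("Source")
        assert table.loc["sequence_type * group", "F"] > \
            table.loc["sequence_type * condition", "F"]
        assert table.loc["group", "F"] > 1.0

    def test_matches_hand_computed_sums_of_squares(self):
        """Balanced 2×2×2 design: F values equal the orthogonal-contrast
        OLS computation done by hand."""
        cells = self._cells(gap_disrupted=0.15, noise=0.05, seed=3)
        y = cells["prop_correct"].to_numpy()
        a = np.where(cells["sequence_type"] == "intact", 1.0, -1.0)
        b = np.where(cells["task"] == "visual", 1.0, -1.0)
        c = np.where(cells["group"] == "TD", 1.0, -1.0)
        X = np.column_stack([np.ones_like(a), a, b, c, a * b, a * c, b * c,
                             a * b * c])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfe = len(y) - 8
        mse = (resid ** 2).sum() / dfe
        ss = len(y) * beta[1:] ** 2  # orthonormal ±1 contrasts, balanced
        f_hand = dict(zip(["sequence_type", "condition", "group",
                           "sequence_type * condition",
                           "sequence_type * group", "condition * group",
                           "sequence_type * condition * group"],
                          ss / mse))
        mine = accuracy_anova(cells).set_index("Source")
        for effect, f_ref in f_hand.items():
            assert mine.loc[effect, "F"] == pytest.approx(f_ref, rel=1e-6)


class TestPosthoc:
    def _cells(self, vals_a, vals_b, task="visual", seq="disrupted"):
        rows = []
        for i, v in enumerate(vals_a):
            rows.append({"participant": f"DCD{i}", "group": "DCD",
                         "task": task, "sequence_type": seq,
                         "prop_correct": v})
        for i, v in enumerate(vals_b):
            rows.append({"participant": f"TD{i}", "group": "TD",
                         "task": task, "sequence_type": seq,
                         "prop_correct": v})
        return pd.DataFrame(rows)

    def test_identical_groups_null_result(self):
        res = posthoc_group_tests(self._cells([0.8, 0.9, 0.7],
                                              [0.8, 0.9, 0.7]))[0]
        assert res.t == pytest.approx(0.0)
        assert res.cohens_d == pytest.approx(0.0)
        assert not res.significant

    def test_hand_computed_three_vs_three(self):
        a, b = [0.70, 0.80, 0.75], [0.90, 0.85, 0.95]
        res = posthoc_group_tests(self._cells(a, b))[0]
        n1 = n2 = 3
        sp = np.sqrt(((n1 - 1) * np.var(a, ddof=1)
                      + (n2 - 1) * np.var(b, ddof=1)) / (n1 + n2 - 2))
        t_hand = (np.mean(a) - np.mean(b)) / (sp * np.sqrt(1 / n1 + 1 / n2))
        d_hand = (np.mean(a) - np.mean(b)) / sp
        assert res.t == pytest.approx(t_hand)
        assert res.df == n1 + n2 - 2
        assert res.cohens_d == pytest.approx(d_hand)

    def test_large_effect_detected_consistently(self):
        """Groups N(0.9, .05²) vs N(0.7, .05²), n = 20: D ≈ 4 and the test is
        significant at α=.01 in every seeded replicate."""
        hits, ds = 0, []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            res = posthoc_group_tests(self._cells(
                rng.normal(0.9, 0.05, 20), rng.normal(0.7, 0.05, 20)))[0]
            hits += res.significant
            ds.append(res.cohens_d)
        assert hits == 10
        assert np.mean(ds) == pytest.approx(4.0, abs=1.0)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="sentinel"):
            res = posthoc_group_tests(self._cells([0.8, 0.8], [0.9, 0.9]))[0]
        assert abs(res.t) >= 1e6

    def test_flag_consistent_with_p_and_alpha(self, rng):
        cells = self._cells(rng.normal(0.8, 0.1, 12),
                            rng.normal(0.75, 0.1, 12))
        for res in posthoc_group_tests(cells, alpha=0.01):
            assert res.significant == (res.p < res.alpha)


class TestLearningSlopes:
    def _trials(self, rts_by_group):
        rows = []
        for grp, rts in rts_by_group.items():
            rows += behavior_rows(f"{grp}01", grp, "visuomotor", 6, 6,
                                  rts=rts)
        return pd.DataFrame(rows)

    def test_constant_rt_gives_zero_slope(self):
        res = learning_slopes(self._trials({"DCD": [900.0] * 12,
                                            "TD": [900.0] * 12}))
        assert np.allclose(res.slopes["slope"], 0.0, atol=1e-12)

    def test_exact_log_linear_rt_recovers_slope(self):
        rts = 1000.0 * np.exp(-0.1 * np.arange(1, 13))
        res = learning_slopes(self._trials({"DCD": rts, "TD": rts}))
        assert np.allclose(res.slopes["slope"], -0.1, atol=1e-12)

    def test_scale_invariance(self):
        cfg = SimulationConfig(seed=5, tasks=("visuomotor",),
                               n_per_group={"DCD": 4, "TD": 4})
        trials, _ = simulate_behavior(cfg)
        res1 = learning_slopes(trials)
        scaled = trials.copy()
        scaled[RT_COLS] = scaled[RT_COLS] * 3.7
        res2 = learning_slopes(scaled)
        np.testing.assert_allclose(res1.slopes["slope"],
                                   res2.slopes["slope"], atol=1e-12)

    def test_nonpositive_rt_trials_excluded_with_warning(self):
        rts = [1000.0] * 12
        trials = self._trials({"DCD": rts, "TD": rts})
        trials.loc[0, "rt_03"] = -5.0
        with pytest.warns(UserWarning, match="non-positive"):
            res = learning_slopes(trials)
        assert res.n_excluded_trials == 1

    def test_group_means_recovered_from_simulator(self):
        cfg = SimulationConfig(seed=7, tasks=("visuomotor",),
                               n_per_group={"DCD": 22, "TD": 23})
        trials, truth = simulate_behavior(cfg)
        res = learning_slopes(trials)
        merged = res.slopes.merge(
            truth.participants[["participant", "rt_slope_log"]],
            on="participant")
        # per-participant estimates track the participant's own true slope
        assert np.corrcoef(merged["slope"],
                           merged["rt_slope_log"])[0, 1] > 0.8


class TestDisruptionRT:
    def test_programmed_cost_recovered_exactly_without_noise(self):
        cfg = SimulationConfig(
            seed=2, tasks=("visuomotor",), n_per_group={"DCD": 5, "TD": 5},
            rt_noise=0.0, rt_slope_sd=0.0, rt_disruption_cost=150.0)
        trials, _ = simulate_behavior(cfg)
        res = disruption_rt_test(trials)
        piv = res.cell_means.pivot_table(index="participant",
                                         columns="sequence_type",
                                         values="rt_ms")
        np.testing.assert_allclose(piv["disrupted"] - piv["intact"], 150.0,
                                   atol=1e-9)

    def test_identical_groups_zero_group_effects(self):
        # slope 0 so positions 10 and 11 share the same base RT: the groups
        # are then exactly identical and only the disruption cost remains
        cfg = SimulationConfig(
            seed=2, tasks=("visuomotor",), n_per_group={"DCD": 6, "TD": 6},
            rt_noise=0.0, rt_slope_sd=0.0,
            rt_slope_log={"DCD": 0.0, "TD": 0.0})
        trials, _ = simulate_behavior(cfg)
        res = disruption_rt_test(trials)
        table = res.anova.set_index("Source")
        assert table.loc["sequence_type", "F"] > 100.0
        assert table.loc["group", "F"] == pytest.approx(0.0, abs=1e-3)
        assert table.loc["Interaction", "F"] == pytest.approx(0.0, abs=1e-3)

    def test_sequence_type_size_under_null(self):
        """No programmed disruption cost → the sequence-type effect rejects
        at roughly the nominal rate."""
        ps = []
        for seed in range(40):
            cfg = SimulationConfig(
                seed=seed, tasks=("visuomotor",),
                n_per_group={"DCD": 8, "TD": 8}, visuomotor_trials=24,
                rt_disruption_cost=0.0)
            trials, _ = simulate_behavior(cfg)
            res = disruption_rt_test(trials)
            ps.append(res.anova.set_index("Source")
                      .loc["sequence_type", "p_unc"])
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= rate <= 0.15

    def test_first_response_test_reported(self):
        cfg = SimulationConfig(seed=3, tasks=("visuomotor",),
                               n_per_group={"DCD": 6, "TD": 6})
        trials, _ = simulate_behavior(cfg)
        res = disruption_rt_test(trials)
        assert {"t", "df", "p", "medians"} <= set(res.first_response)


def test_significance_flags_recomputable_from_printed_stats(rng):
    """Every post-hoc flag can be reproduced from its own printed t and df."""
    rows = []
    for grp, mu in (("DCD", 0.75), ("TD", 0.9)):
        for i in range(15):
            rows.append({"participant": f"{grp}{i}", "group": grp,
                         "task": "visual", "sequence_type": "disrupted",
                         "prop_correct": rng.normal(mu, 0.08)})
    for res in posthoc_group_tests(pd.DataFrame(rows)):
        p_re = 2 * stats.t.sf(abs(res.t), res.df)
        assert res.p == pytest.approx(p_re, rel=1e-9)
        assert res.significant == (p_re < res.alpha)
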