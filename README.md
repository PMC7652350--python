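# seqerp

ERP and behavioral analysis of **serial prediction tasks (SPTs)** in
two-group developmental studies — built for researchers comparing, e.g.,
children with Developmental Coordination Disorder (DCD) against
typically-developing (TD) controls on sequence-violation paradigms.

In an SPT, short two-element sequences repeat six times per trial and are,
on half of the trials, disrupted at stimulus position 10 or 11; the
participant judges after each trial whether the sequence was disrupted.
Disruptions elicit a **P3**: a positive ERP deflection over centro-parietal
sites (Pz) roughly 400–1000 ms after the violating stimulus, taken as an
index of stimulus evaluation and the updating of an internal forward model.
The analytically interesting group effect is typically a *latency* shift of
this component, not an amplitude change — which calls for the specific
chain of methods this package implements:

- **Preprocessing** — 0.1–40 Hz Hamming windowed sinc FIR band-pass (zero
  delay), epoching over −250..1000 ms around the disruption-locked marker
  (shifted +300 ms for duration-defined sequences), −250..0 ms baseline,
  semi-automatic ±100 µV artifact rejection, exclusion of participants with
  fewer than 10 usable trials in either condition, and correct-trial
  averaging by sequence type.
- **Cluster-based temporal permutation test** (single electrode). Paired
  *t* at every timepoint on the disrupted−intact differences; clusters =
  maximal same-sign runs with |t| above the two-sided α = .05 criterion;
  cluster mass = Σt; the null is the max |mass| under per-participant sign
  flips (exhaustive enumeration when 2ⁿ ≤ the permutation budget, otherwise
  Monte Carlo with the +1 correction).
- **Percent-area latency + jackknife inference.** The 50%-area latency is
  the time *t*\* with ∫ᵗ*\* w₊ dt = ½ ∫ w₊ dt over the measurement window
  (w₊ = positive-rectified difference wave). Group inference uses
  leave-one-out scoring: latencies of N grand averages each omitting one
  participant, a one-way ANOVA on those replicates, and the adjustment
  **F_adj = F / (N−1)²** that undoes the (N−1)² variance shrinkage of
  jackknife replicates.
- **Behavioral analyses** — proportion-correct cells with a
  SequenceType × Condition × Group ANOVA and α = .01 post-hoc group tests
  (pooled-variance t, Cohen's D); visuomotor RT learning as the OLS slope
  of log median RT over responses 1–9 with a Welch group comparison; and a
  SequenceType × Group mixed ANOVA (generalized η²) on RTs at the
  disrupting stimulus.
- **Synthetic-data generator** with known ground truth (Gaussian P3 bump on
  1/f + white noise; Bernoulli accuracy; power-law RT learning) so that
  every stage can be validated by parameter recovery.

## Worked example

Group latencies per condition feed a one-line delay summary. With a
latency table holding, per condition, the DCD and TD 50%-area latencies
(Control 791/694, Motor 854/751, Spatial 757/703, Visual 856/774 ms):

```python
import pandas as pd
from seqerp import mean_group_delay

table = pd.DataFrame(
    [("DCD", "Control", 791.0), ("TD", "Control", 694.0),
     ("DCD", "Motor",   854.0), ("TD", "Motor",   751.0),
     ("DCD", "Spatial", 757.0), ("TD", "Spatial", 703.0),
     ("DCD", "Visual",  856.0), ("TD", "Visual",  774.0)],
    columns=["group", "condition", "latency_ms"])
print(mean_group_delay(table, ["Control", "Motor", "Spatial", "Visual"]))
```

```
84.0
```

i.e. the P3 to sequence disruptions is on average 84 ms later in the DCD
group. The full simulated chain, from raw epochs to that number:

```python
import numpy as np
from seqerp import (SimulationConfig, simulate_epochs, preprocess_epoch_sets,
                    jackknife_latencies, adjusted_group_test)
from seqerp.pipeline import _difference_waves

cfg = SimulationConfig(seed=1, tasks=("visual",),
                       n_per_group={"DCD": 20, "TD": 20})
epochs, truth = simulate_epochs(cfg)          # ground-truth gap: 84 ms
pre = preprocess_epoch_sets(epochs)           # baseline→reject→exclude→avg
lat = {}
for (task, grp), waves in _difference_waves(pre.erps).items():
    arr = np.vstack([w.values for w in waves])
    lat[grp] = jackknife_latencies(arr, waves[0].times, (400, 1000))
test = adjusted_group_test(lat["DCD"].jackknife_replicates,
                           lat["TD"].jackknife_replicates)
print(f"gap = {lat['DCD'].latency_ms - lat['TD'].latency_ms:.1f} ms, "
      f"F_adj({test.df[0]},{test.df[1]}) = {test.F_adjusted:.2f}, "
      f"p = {test.p:.2e}")
```

```
gap = 90.9 ms, F_adj(1,18) = 33.55, p = 1.73e-05
```

The estimated gap fluctuates around the programmed 84 ms with the sampling
noise of 20 participants per group; the adjusted F is the jackknife ANOVA F
divided by (N−1)² = 361.

There is also a CLI: `seqerp simulate|preprocess|cluster-test|latency|`
`behavior|run-all`, each logging all parameters it used; `seqerp run-all
--seed 1 --out out/` writes `summary.json`, cluster/latency/accuracy/slope
tables and an exclusion report.

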