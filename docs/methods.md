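# Methods

This note records the models, numerical choices and limitations behind
`seqerp`, at the level of detail a user needs to judge what a passing test
suite does and does not establish.

## The analysis chain

The package analyses two-group serial-prediction-task (SPT) studies: each
trial presents six repetitions of a two-element sequence, half of the
trials are disrupted at stimulus position 10 or 11, and the quantities of
interest are (i) the late parietal positivity (P3) elicited by the
disrupting stimulus in the EEG at Pz, and (ii) behavioral accuracy and,
for the visuomotor task, per-stimulus reaction times. The pipeline order
is fixed — filter → epoch → baseline → reject → exclude → average →
cluster test → latency/jackknife — and every step is a pure function of
its inputs, so reruns are bit-identical.

## Preprocessing

**Band-pass filter.** Hamming windowed sinc FIR, pass band 0.1–40 Hz,
applied once with its group delay compensated (odd-length linear-phase
kernel; edges handled by repeated odd reflection). The transition
bandwidth follows the common heuristic min(max(f/4, 2 Hz), f): 0.1 Hz at
the low edge and 10 Hz at the high edge, giving a ~16 501-tap kernel at
500 Hz. A 1 Hz transition at the low edge was considered and rejected: it
cannot deliver meaningful attenuation at 0.01 Hz when the cutoff itself is
0.1 Hz, and drift suppression is the point of the high-pass. The contract
tested is ≥ 20 dB attenuation at 0.01 Hz and at 80 Hz, ≤ 5% ripple at
10 Hz.

**Epoching.** Windows are specified in ms, closed at both ends, and
resolved to the nearest sample; time 0 is the event marker plus an
optional shift (+300 ms for duration-defined sequences, where intact and
disrupted trials only become distinguishable after the shorter stimulus
has elapsed). The −250..0 ms baseline stays relative to the *shifted*
zero. Events too close to a recording edge are flagged rejected, never
silently dropped.

**Rejection and exclusion.** A trial is auto-flagged iff any sample
satisfies |v| > 100 µV (strict inequality, so a trial touching exactly
±100 µV survives); an externally supplied trial blacklist models the
manual half of a semi-automatic procedure — there is no interactive UI. A
participant is retained for a task iff both sequence types keep ≥ 10
usable trials (≥ is inclusive: 10-of-10 is kept). Averages use correct,
non-rejected trials only.

## Cluster-based permutation test

Single-electrode, temporal-contiguity-only clustering on per-participant
disrupted−intact difference waveforms. The forming threshold is the
two-sided t criterion at cluster α = .05 with n−1 df; clusters are maximal
contiguous same-sign suprathreshold runs; the cluster statistic is the
mass (sum of t). The null distribution is the maximum |mass| under random
per-participant sign flips; with 2ⁿ ≤ the permutation budget all 2ⁿ
patterns are enumerated and p = #{null ≥ |mass|}/2ⁿ (the identity pattern
is included, so p ≥ 2⁻ⁿ⁺¹ for symmetric designs); otherwise p uses the
Monte-Carlo +1 correction, p = (1 + #{null ≥ |mass|})/(1 + n_perm), which
cannot reach zero. The forming α and the 2000-permutation default are
assumptions (recorded in every result's metadata), since the choice is
conventionally left unstated. Zero-variance timepoints with nonzero mean
map t to a finite ±10⁶ sentinel with a warning rather than ±∞.

Permutation t-series are computed in a vectorized form exploiting the
sign-flip invariance of per-timepoint sums of squares, so the 500-dataset
calibration simulation in the test suite runs in seconds.

## Percent-area latency and jackknife inference

The 50%-area latency rectifies the difference wave to positive polarity
(the P3 is a positivity; negative excursions are zeroed, not folded),
accumulates trapezoidal area across the measurement window, and returns
the first crossing of half the total area, linearly interpolated between
the bracketing samples. Zero total area raises an explicit error instead
of propagating NaN. The measurement window is, per condition, the union
span of significant clusters clipped to the 400–1000 ms P3 window, falling
back to 400–1000 ms when nothing is significant.

Jackknife scoring computes the latency on N leave-one-out grand averages
per group. Because leave-one-out means of n values have variance
s²/(n−1)², a one-way ANOVA on the replicates inflates F by (n−1)² exactly
for equal group sizes; the adjustment F_adj = F/(N−1)² undoes it. **N
convention:** N is the per-group replicate count when group sizes are
equal — the convention under which the adjustment is exactly calibrated —
and the rounded mean group size otherwise (approximate; exact rescaling is
impossible with a single N when n₁ ≠ n₂). Every result records which N
was used and an override is exposed. The p-value refers F_adj to
F(1, N−2), which is mildly conservative (the equal-group sampling
distribution is closer to F(1, 2n−2)); simulated null rejection at α=.05
is ≈ 0.03–0.09 under the default study conditions.

## Behavioral analyses

Accuracy cells are proportions correct per participant × task × sequence
type, after the same ≥ 10-responses-per-condition rule. The omnibus ANOVA
treats SequenceType, Condition and Group as crossed fixed factors on the
pooled cell table with Type III sums of squares — the df structure this
produces (error df ≈ number of cells minus model df) matches how such
designs are commonly reported for unbalanced developmental samples; a
subject-level mixed model would be the stricter alternative and is
deliberately out of scope. Post-hoc group comparisons use pooled-variance
Student t with df = n₁+n₂−2 and pooled-SD Cohen's D at α = .01 (Welch
available via `equal_var=False`).

RT learning: per participant, the median RT per response index over all
visuomotor trials (intact and disrupted pooled — per-index medians, not
raw trials, so single slow responses do not dominate), log-transformed and
regressed on index 1..9 by OLS; group slopes compared with a Welch t-test.
Trials containing a non-positive RT are excluded with a log entry. The
slowing at the disrupting stimulus compares, within participant, RTs at
the disruption position on disrupted trials with the same positions on
intact trials, weighted by the participant's disrupted-position counts so
both sequence types are measured at identical positions; the
SequenceType × Group mixed ANOVA reports generalized η² and is
accompanied by a Welch t-test on first-response median RTs.

## Synthetic data generator

The generator emulates the study design it is meant to stress: groups of
24 (DCD) and 23 (TD) children, five tasks (control, spatial, temporal,
visual, visuomotor), 60 trials per task (72 visuomotor), half disrupted at
position 10 or 11 (uniformly — the ratio is a free choice, as only the
existence of both positions is given), single-channel 500 Hz epochs over
−250..1000 ms.

* **P3**: a Gaussian bump (SD 80 ms) — the simplest shape whose
  fractional-area latency has a closed form (the center). Amplitude per
  group × sequence type (defaults 10 µV disrupted / 2 µV intact, equal
  across groups, matching the absence of an amplitude group effect);
  participant latency ~ N(group mean, 30 ms) with group means 700 ms (TD)
  and 784 ms (DCD), i.e. a programmed 84 ms delay; single-trial jitter
  SD 40 ms (a free parameter — single-trial jitter is never reported — and
  exposed in the config).
* **Noise**: 1/f^α background (α = 1, the standard EEG approximation,
  synthesized by spectral shaping with an analytic Parseval normalization)
  at 12 µV plus 8 µV white noise; an optional 5% of trials carry a ±150 µV
  square glitch to exercise rejection.
* **Behavior**: correctness ~ Bernoulli per group × sequence type
  (defaults 0.93/0.88 intact and 0.88/0.76 disrupted for TD/DCD,
  consistent with overall intact/disrupted means near .91/.82);
  correctness is drawn independently of the EEG signal, since the two are
  linked downstream only through correct-trial averaging, not by any
  generative claim. Visuomotor RTs follow
  log RT = log(1000 ms) + slope·k + ε, ε ~ N(0, 0.25²), slope per
  participant ~ N(group mean, 0.02) with group means −0.098 (DCD) and
  −0.075 (TD), plus 150 ms at the disrupting stimulus.

What the generator does **not** emulate: blinks and saccades (hence no
ICA stage — on real data, run blink removal upstream), multi-electrode
topography and volume conduction, autocorrelated latency drift across
trials, non-stationary noise, response-omission patterns, or any coupling
between neural signal quality and behavioral accuracy. Recovery tests
therefore validate the estimators under the stated statistical model; they
do not certify robustness to artifacts the model lacks.

## Problem sizes used in validation

Calibration and recovery runs are sized for desk-scale reproducibility:
the cluster-test false-positive rate uses 500 null datasets (12
participants, 626 timepoints, 200 permutations each); latency-gap recovery
and the adjusted test's null size use 100 simulated studies of 20
participants per group with 30 artifact-free trials per condition;
learning-slope recovery uses 100 studies at n = 22/23. The acceptance
script runs slightly smaller replicates (60/40) of the same checks plus
one full-scale simulated study.

## Known limitations

* The jackknife adjustment's N is approximate for unequal group sizes
  (see above); results record the convention used.
* The exhaustive/Monte-Carlo switch compares 2ⁿ to the permutation budget;
  for n ≤ 10 at the 2000-permutation default the test is exact.
* The accuracy ANOVA on pooled cells ignores the participant factor's
  covariance structure (see above).
* BrainVision reading supports the common single-file layouts MNE handles;
  writing BrainVision is out of scope — simulated epochs are exchanged in
  a plain TSV matrix + metadata format.
* Latency measurement assumes a positive-going component; purely negative
  difference waves require `polarity="negative"`.
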