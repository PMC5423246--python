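# Methods

## The analysis model

Each animal contributes one time course per assay over observation days
`d_0 = 0 < d_1 < … < d_k` (default {0, 3, 5, 7}; day 0 is the pre-surgery
baseline). The whole-period effect is the trapezoidal AUC over the
*observed* days, day 0 included. Including day 0 anchors every arm at its
pre-surgery response, which makes the vehicle/sham contrast well defined at
baseline; it is a frozen convention, and an animal missing a scheduled day
is flagged (and its AUC uses only its observed days) rather than imputed or
silently dropped.

Three effect statistics are used, one per assay:

* **raw AUC** (von Frey PWT, g×days) — no normalization;
* **percent inhibition** (acetone PWF) — `PI_i = 100·(v̄ − AUC_i)/v̄` with
  `v̄` the vehicle arm's mean AUC;
* **%MPE** (radiant-heat PWL) — `MPE_i = 100·(AUC_i − v̄)/(s̄ − v̄)` with
  `s̄` the sham arm's mean AUC.

The reference quantities are arm-level *means*, so both scores are affine
in the animal's own AUC: the group mean score equals the score of the group
mean AUC, per-animal scores carry the group SEM, and the vehicle arm scores
exactly 0 (sham exactly 100 on %MPE) by construction. Scores are not
clamped; worsening is negative, better-than-sham exceeds 100.

## Additive null and classification

For a combination arm with mono-therapy components A and B the additive
expectation is `E = mean_A + mean_B` with reported SEM `√(s_A² + s_B²)`
(independent arms). The observed combination effect is compared with E by a
Welch-style t-test in which the expectation is an *estimate*, not a
constant: its variance and Welch–Satterthwaite degrees of freedom come from
the two mono arms.

**Reference-arm error propagation.** For PI and %MPE the reference means
(`v̄`, and `s̄ − v̄`) appear in every score; in the observed-minus-expected
contrast the vehicle mean survives with a net coefficient of one, so its
sampling error does not cancel. With equal arm variances this inflates the
contrast variance by ~4/3 over the naive `s_obs² + s_A² + s_B²` sum, and in
Monte-Carlo runs at n = 6 it pushed the false non-additive rate from ~4% to
~8% at nominal α = 0.05. The test therefore adds first-order (delta-method)
variance terms for the reference means — gradients `(Δ + 100)/v̄` (PI) and
`(100 + Δ)/(s̄ − v̄)`, `−Δ/(s̄ − v̄)` (%MPE), with Δ the contrast on the
score scale — each entering the Welch–Satterthwaite pooling with its arm's
n − 1 df. The SEM *printed* for the expected effect in tables remains the
conventional `√(s_A² + s_B²)`; the adjustment affects only the test. After
the adjustment the measured false non-additive rate at n = 6 is ~5%.

Labels: `potentiated` if observed > expected with p < α, `sub_additive` if
observed < expected with p < α, `additive` otherwise (α = 0.05, two-sided,
no multiplicity correction across the combination × assay cells; a
Bonferroni-style correction can be applied by lowering α). Published tables
in this field sometimes label by the raw direction regardless of
significance; `rule="raw"` reproduces that convention. No isobolographic
analysis is attempted — the null is the sum of effects, not dose
equivalence.

Note on the raw-AUC statistic: summing two mono-therapy *raw* AUCs counts
the untreated baseline response twice, so the additive "expectation"
usually sits near the sham ceiling and combinations classify as
sub-additive unless they nearly normalize the animal. This is a property of
the published procedure, reproduced deliberately; the normalized statistics
(PI, %MPE) do not share it.

## Significance tests

* Time courses: pingouin's mixed two-way ANOVA (arm between animals, day
  repeated within), complete-case — animals missing any day are dropped
  with a warning. Post-hoc family: each non-control arm vs the control at
  each day, Student t with Bonferroni multiplier m = (arms − 1) × days.
* Per day: Kruskal–Wallis omnibus; if p < α, Mann–Whitney U of each arm vs
  control, exact when both n ≤ 8 and no ties are present (the exact null
  has no tie correction), otherwise the normal approximation with midrank
  tie handling; Bonferroni over the (arms − 1) contrasts. All values
  identical returns H = 0, p = 1.

## Synthetic generator

`value(day) = baseline + sign·amplitude·trajectory(day)·(1 − relief) + ε`,
with per-animal Gaussian baselines, per-observation Gaussian noise ε,
censoring into [0, cutoff], and integer rounding for the acetone count.
Relief is the fraction of the injury component reversed:
`Emax·dose/(dose + ED50)` for a single drug, and
`min(1, (r_A + r_B)(1 + γ))` for a combination — γ = 0 is exactly additive
on the relief scale, the cap at 1 prevents super-sham responses, and drugs
act multiplicatively on the injury so sham animals are unaffected. One
random stream per arm (keyed off the global seed by arm index) keeps
existing arms' data invariant when arms are added.

Default study (frozen after one tuning pass): 17 arms × 6 animals, days
{0, 3, 5, 7}, trajectory (0, 0.8, 0.95, 1.0) — injury near-plateau within
the week; von Frey baseline 15 ± 1.2 g, amplitude 13 g, noise 1.0 g
(vehicle mechanical AUC ≈ 40 a.u., sham ≈ 105 a.u.); acetone latent count
baseline 0.5 ± 0.3, amplitude 4.0, noise 0.6; radiant heat baseline
12 ± 1 s, amplitude 7 s, noise 0.8 s. Dose-response defaults
(amitriptyline Emax 0.9/ED50 12; extracts Emax 0.85/ED50 140 and 160
mg/kg) make 3 mg/kg amitriptyline and 25 mg/kg extract sub-effective while
30 and 100 mg/kg produce clear effects. Default γ: 0 for the 25 mg/kg
combinations, 0.4–0.6 for the 50/100 ones. An optional gabapentin
positive-control arm (100 mg/kg; schedule invented, as none is standard
for this design) is off by default.

What the generator does *not* emulate: pharmacokinetics, within-day
repeated stimulation, sedation or other side effects, ordinal granularity
of von Frey filament sets (thresholds are continuous), inter-animal
correlation beyond the baseline shift, and attrition. Passing tests
therefore demonstrate the *statistical machinery* — not that real CCI data
satisfy the generator's assumptions.

## Calibration scenario

The classifier's operating characteristics are measured on a minimal
five-arm radiant-heat study (sham, vehicle, two monos at relief 0.25 each,
one combination), n = 6, analyzed on %MPE — the baseline-referenced
statistics are the only ones for which relief-scale additivity maps to an
exact additive null (raw AUC provably cannot, for any valid trajectory,
without censoring bias). Frozen constants: baseline 12 ± 0.5 s, amplitude
7 s, noise 0.8 s. Under γ = 0 the non-additive label rate estimates type-I
error; under γ = 0.9 the true combined relief is 0.95 (cap not binding), a
true %MPE of 95 vs an expected 50 — about 5–6 propagated SEMs, so the
potentiated-label rate estimates power well inside the detectable regime.
500 replicates keep the Monte-Carlo SE near 1 percentage point at rates
near 5% while the whole calibration finishes in well under a minute.

## Numerical and edge-case conventions

* SEM = sample SD (ddof 1)/√n; arms need n ≥ 2.
* Degenerate t-test variance: zero total SE gives p = 1 for equal means,
  p = 0 otherwise; Welch–Satterthwaite terms with zero variance or df are
  skipped, and an infinite df falls back to the normal tail.
* PI requires vehicle mean AUC > 0; %MPE requires sham ≠ vehicle mean.
* Acetone counts are rounded half-to-even then clamped to {0..5};
  validation rejects non-integer counts on input.
* CSV round trips are exact (`float_precision="round_trip"` on read,
  deterministic sort on write).
* Table rendering: one decimal place, three significant digits below 1.

## Known limitations

* The expected-effect SEM printed by the original tables in this field is
  not reproducible by any standard propagation; `√(s_A² + s_B²)` is the
  defensible convention and is what the package reports.
* The reference-arm delta-method adjustment is first order; at very small
  sham−vehicle separation the %MPE scale itself becomes unstable and the
  test inherits that.
* The mixed ANOVA is complete-case; there is no mixed-model handling of
  missing days.
* Group-level reference cells (see `reference_tables`) cannot validate
  per-animal quantities; they check arithmetic and classification logic
  only.
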