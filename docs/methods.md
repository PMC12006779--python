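# Methods

## Problem setting

`equisense` quantifies *measurement equivalence* in a
bring-your-own-device (BYOD) setting: whether the scalar performance
features of six smartphone active tests — Information Processing Speed
(IPS, 90 s), its digit-digit variant (IPS DD, 30 s), the Pinching Test
(PT, 30 s), the Static Balance Test (SBT, 30 s), the U-Turn Test (UTT,
≤60 s window) and the 2-Minute Walk Test (2MWT, 120 s) — are
distributed identically across device-defined participant subgroups.
The null hypothesis for every comparison is exchangeability of a
subgroup with the pooled remainder of its category.

## Synthetic data generator

No participant data ship with the package; the generator produces
cohorts and raw sensor sessions with known ground truth so that every
downstream stage is testable.

**Cohort model.** Participants draw a platform (default iOS share
0.817, matching the strongly iOS-skewed fleets typical of early BYOD
deployments), a device model from a within-platform catalog (14 models
including two tablets; Android models carry higher touch latency,
90–140 ms vs 20–40 ms, and several sample at 50 Hz instead of 100 Hz),
an OS version, age ~ N(43, 12.5²) truncated at 18, sex (63% female)
and disease status (58% MS).

**Performance model.** Each participant owns one stable target value
per test, drawn from `baseline + age·slope + sex·offset + MS·offset +
N(0, σ)`. Baselines and spreads follow the cohort-level feature
distributions reported for these six tests (IPS 43.8 ± 11.9 correct,
PT 30.8 ± 13.5 pinches, SBT 21.8 m/s², UTT 1.40 rad/s, 2MWT 190 ± 38
steps); the MS offsets reproduce the reported MS vs non-MS gaps. The
target parameterizes the raw signal: response rate, pinch rate, sway
amplitude, turn speed, walking cadence.

**Signal models** are the simplest closed forms from which the
extractors can provably recover the programmed truth:

* *Gait* (2MWT, and the UTT accelerometer): vertical acceleration =
  g + A·sin(2πft) + 0.3A·sin(4πft+φ) + band-limited noise, A = 2 m/s²,
  noise SD 0.2 m/s². One sinusoid peak per step; the programmed count
  on [0, T) is ⌊fT − 0.25⌋ + 1.
* *Turns* (UTT gyroscope): yaw-rate boxcar pulses, angle = rate ×
  width exactly; default five alternating 180° turns at 1.5 rad/s.
  Gyroscope noise SD 0.02 rad/s, chosen so that integrating noise
  across a ~2 s turn stays well inside the ±2° recovery tolerance.
* *Quiet stance* (SBT): planar circular sway acceleration of radius A
  at 1 Hz (closed-form path 2πAfT) over g plus smooth vertical noise
  (SD 0.3 m/s², low-passed at 0.8 Hz — white noise would add unbounded
  length to the acceleration path, which real, band-limited
  accelerometer noise does not).
* *Phone on table*: gravity plus a 0.02 m/s² microtremor, an order of
  magnitude below the 0.1 m/s² stillness threshold and two below
  handheld stance.
* *Pinches*: two-pointer gestures closing to 10% of their initial
  separation on a steady schedule. Each completed pinch costs the
  device's latency L on top of the pinch period p, so the cumulative
  latency eats the tail of the window: the generated count is
  n₀ − ⌊n₀·L/p⌋ with n₀ the latency-free count. At 1 pinch/s and
  L = 100 ms this is exactly 3 pinches over 30 s.
* *Symbol tests*: scripted response logs at the participant's rate
  with accuracy 0.9 against an n-option key (n defaults to 9 but is a
  parameter, since the real key size is not fixed by the design).

**Anomaly modes** rewrite a clean session and label it: `low_rate`
(resample at 25 Hz), `unstable_rate` (a 2 s window thinned to 20 Hz),
`play_to_quit` (responses independent of the shown symbol at 120 ms
pacing, or an empty touch log), `phone_on_table`, `short_test`
(truncate the UTT to 35 s, the walk to 95 s). Session-level anomaly
rates default to 1–5%; additionally 1.7% of participants draw a
persistently undersampling device, the mode that removes whole
participants at the rate-check step. A `flip_orientation` helper
rotates the gravity axis for a fraction of a session to build labeled
fixtures for the orientation flag.

All draws descend from a single seed through keyed `SeedSequence`
children (participant id, test, run index), so cohorts, sessions and
feature tables are bitwise reproducible and a session can be
regenerated in isolation.

**What the generator does not emulate:** real gait variability
(cadence drift, asymmetry), device-specific IMU noise spectra and
calibration error, screen-size ergonomics, scheduling adherence, or
learning effects across repeated tests. Passing recovery tests
therefore demonstrates the internal consistency of the
generator–extractor–statistics chain, not clinical validity of the
feature algorithms on real recordings.

## Quality control

Step 1 excludes any session whose stream has a global mean rate
≤ 33 Hz or any sliding-window local rate ≤ 33 Hz. The window is 1 s
with a 0.5 s step — the shortest gait-relevant timescale; the
criterion is inclusive (exactly 33 Hz fails), as are all QC
inequalities below.

Step 2 applies per-test flags; a session is valid iff the rate check
passes and no flag is raised:

| test | flag | rule (defaults) |
|---|---|---|
| IPS, IPS DD | play_to_quit | accuracy indistinguishable from chance 1/n (one-sided binomial p > 10⁻³) **and** median inter-response interval < 0.5 s |
| PT | no_touch | zero touch events |
| SBT/UTT/2MWT | phone_on_table | acceleration-magnitude SD < 0.1 m/s² and mean within 5% of g |
| SBT | steps_during_sbt | step detector count ≥ 2 |
| UTT | orientation_unstable | modal dominant gravity axis (first-order 0.5 Hz low-pass) on ≤ 90% of samples |
| UTT | too_few_turns / bad_turn_angle / too_short | turns ≤ 3; any angle ≤ 90° or ≥ 270°; duration ≤ 40 s |
| 2MWT | too_short | duration ≤ 105 s |

The two-condition play-to-quit rule is deliberate: chance-level
accuracy alone would misclassify impaired but accordant users, and
fast pacing alone would misclassify quick accurate ones. The
step-limit of 2 reads "steps recorded" as "more than an isolated
transient". Both operationalizations are configurable in
`QCThresholds`.

## Feature extraction

* **Correct responses** — entries whose selected digit equals the
  key's mapping of the shown symbol, within the test window.
* **Pinch count** — completed two-pointer gestures whose inter-pointer
  distance shrinks by ≥ 30% between first co-touch and release
  (success is not defined by the source design; the closure fraction
  is a documented parameter).
* **Sway path** — total path length of the acceleration trajectory
  after gravity removal: Σ‖Δa‖ over consecutive samples, in m/s².
  Gravity is the per-axis zero-phase 4th-order 0.5 Hz low-pass
  component. This is the standard accelerometric sway-path definition
  consistent with the m/s² unit; it is *not* normalized by duration.
* **Turn detection** — contiguous runs of |yaw| > 0.3 rad/s (below any
  plausible U-turn, above sensor noise), merged across sub-threshold
  dips < 0.2 s and extended one sample into the sub-threshold
  boundary so the partial edge intervals integrate too; angle by
  trapezoidal integration, per-turn mean rate = angle/duration.
  **Turn speed** is the mean of per-turn mean rates (per-turn
  averaging chosen over pooling all in-turn samples; with near-boxcar
  turns the two agree).
* **Step count** — band-pass (0.5–3 Hz, 2nd-order Butterworth,
  zero-phase) the acceleration magnitude and count peaks above
  max(0.5 m/s², half the filtered SD) with ≥ 0.25 s separation. The
  absolute floor keeps stance noise at zero steps; the detector is
  deliberately simple because its contract is synthetic-truth
  recovery.

Features exist only for valid sessions; requesting one for an invalid
session raises.

## Statistics

**First-valid selection.** The five bundled tests are taken from the
earliest run in which all five are valid — a run with four valid tests
contributes nothing (completed-run semantics). The walk is selected
independently as the first valid 2MWT.

**Covariate adjustment** fits, per test, a Huber M-estimated linear
model of the feature on age, sex and MS status (tuning constant 1.345,
95% Gaussian efficiency — the design names only "a robust linear
model"). Covariates are centered so that adjusted = intercept +
residual keeps the native scale. Adjustment is fit once per test
across all participants (not per platform), so device-related
differences are preserved for the equivalence test itself.

**Permutation engine.** p = (1 + #{|Δ*| ≥ |Δ|})/(B+1), two-sided on
absolute differences with the add-one correction: it cannot return 0,
is valid for any B, and converges to the plain proportion of larger
permuted differences as B → ∞. The null interval is the (α/2,
1−α/2) quantile pair of |Δ*| — a nonnegative range of differences
expected under exchangeability. Mean sub-sums are computed by
`argpartition` over chunks of at most ~4·10⁶ pooled values, which keeps
10,000 permutations of a 1,500-participant comparison under a second;
the median statistic (sensitivity analysis) uses full permutations.
Ties at exactly |Δ| count as extreme (≥ with a 10⁻¹² guard).

**Families for FDR.** Benjamini–Hochberg is applied within each
(test × category) family, matching the per-test blocks in which
adjusted p-values are conventionally reported; the family definition
is not fixed by the design and is configurable in spirit (it lives in
one loop of `run_equivalence`).

**Cohen's d** uses the df-weighted pooled SD; the percent-difference
denominator is the reference-group mean. With zero pooled SD the
effect size is reported undefined rather than infinite.

**Screen size** (smartphone vs tablet) is a separate per-test
Mann-Whitney U comparison — exact enumeration for combined n ≤ 12
without ties, tie-corrected normal approximation otherwise — kept
outside the permutation loop because it answers a different question
(two fixed hardware classes, not one subgroup against its pooled
complement).

**Seeding.** The pipeline seed fans out via
`SeedSequence(seed).generate_state` to per-stage child seeds (all
< 2³¹); inside `run_equivalence` each comparison consumes one spawned
child in a fixed iteration order, so reports are byte-identical across
reruns.

## Problem sizes and defaults

The default pipeline cohort is 300 participants (a scale at which the
platform subgroups qualify under the ≥ 20 rule while a full
synth→QC→features→analyze run takes well under a minute); statistics-
scale experiments bypass signal synthesis through
`generate_feature_table`, which draws features directly from the
performance model (with optional per-subgroup mean shifts recorded as
ground truth). Calibration experiments in the test suite use 2,000
null simulations at group sizes 50/500 with 2,000 permutations each;
effect-recovery experiments use 100 replicates at 338 vs 1,233 with
10,000 permutations.

## Known limitations

* Feature extractors are truth-recovery instruments for the synthetic
  signal families, not validated clinical algorithms; the pinch
  closure fraction, turn onset threshold and step-peak floor would all
  need re-tuning on real recordings.
* The permutation test assumes exchangeability under the null;
  covariate adjustment removes modeled confounding only (age, sex,
  disease status — not disease severity, which BYOD studies typically
  cannot observe).
* Percent differences are reported against the reference mean and are
  unstable when that mean approaches zero (an error is raised at
  exactly zero).
* The equivalence analysis is descriptive: failing to reject the null
  is not a formal demonstration of equivalence, which would require
  prespecified margins (e.g. TOST) and is out of scope.
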