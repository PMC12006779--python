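# equisense

Measurement-equivalence analysis for smartphone sensor–based tests in
bring-your-own-device (BYOD) studies.

When a remote study lets participants use their own phones, every
feature — correct responses on a processing-speed test, pinches in a
dexterity task, sway path during quiet stance, turn speed, step count —
is measured through heterogeneous hardware: two OS platforms, dozens of
OS versions, hundreds of device models, different IMU sensors, sampling
rates and touchscreen latencies. Before such features can be pooled or
compared across participants, one must check that a device-defined
subgroup does not systematically shift the measurement. `equisense`
implements that check as a reproducible pipeline, together with a
synthetic-data generator that makes every stage testable without any
participant data.

## What it computes

For each active test and each subgroup *g* of a category (OS platform,
iOS version, Android version, device model), with pooled reference
group *r* (all other qualifying subgroups of the category, subgroups
with n < 20 excluded from both roles):

1. **First-valid selection** — each participant contributes the feature
   values of their first test run in which all five bundled tests were
   valid, plus their first valid 2-minute walk.
2. **Covariate adjustment** — features are adjusted for age, sex and
   self-declared disease status with a Huber robust linear model
   (tuning constant 1.345); adjusted value = intercept + residual, so
   values keep their native scale.
3. **Permutation test** — with Δ = x̄_g − x̄_r (or the median difference
   in the sensitivity analysis), the pooled values are randomly re-split
   B = 10,000 times at the original group sizes and

   p = (1 + #{|Δ*_b| ≥ |Δ|}) / (B + 1).

   The 95% interval of |Δ*| quantifies the differences expected under
   the null.
4. **Effect sizes** — Cohen's d = |x̄_g − x̄_r| / s_pooled (df-weighted
   pooled SD), absolute and percent differences, and
   Benjamini–Hochberg FDR-adjusted p-values within each
   (test × category) family.

Upstream, the quality-control stage discards sessions with a low or
unstable sampling frequency (global or any 1 s window ≤ 33 Hz) and
applies per-test validity flags (play-to-quit responding, no screen
interaction, phone on the table, steps during the balance test,
unstable orientation, too few turns, implausible turn angles, truncated
gait tests). Smartphones vs tablets are compared separately with a
Mann-Whitney U test.

## Worked example

```sh
equisense run --seed 7 --out report/
```

runs the full pipeline on a synthetic 300-participant cohort (the
built-in generator defaults) and prints the participant accounting:

```
{"participants_in": 300, "excluded_rate": 0, "excluded_no_valid_test": 20, "analyzed": 280}
```

300 participants entered; none were excluded at the sampling-frequency
step (the cohort is small enough that no persistently undersampling
device was drawn); 20 never produced a fully valid test run; 280 were
analyzed. `equisense render --comparisons report/comparisons.csv`
formats the subgroup comparisons; the Android-vs-iOS rows:

```
  test subgroup  n    mean (SD) reference mean (SD) absolute difference percent difference effect size   95% CI p unadjusted p adjusted
   IPS  Android 33   43.4 (9.1)         43.4 (11.5)                 0.0                0.0        0.00  0.1-5.0        0.992      0.992
IPS_DD  Android 33   18.5 (3.7)          16.9 (3.5)                 1.6                9.4        0.45  0.0-1.5        0.020      0.020
    PT  Android 33   28.0 (7.9)         29.0 (11.0)                 1.0                3.3        0.09  0.1-4.4        0.638      0.638
   SBT  Android 33  32.0 (12.9)         32.7 (13.8)                 0.7                2.1        0.05  0.1-5.7        0.777      0.796
   UTT  Android 33    1.4 (0.3)           1.4 (0.3)                 0.0                1.5        0.06  0.0-0.1        0.722      0.726
  MWT2  Android 39 185.9 (30.1)        185.4 (35.9)                 0.5                0.3        0.02 0.2-13.5        0.927      0.927
```

This cohort is simulated with no platform effect, so observed
differences are sampling noise: effect sizes are very small to small,
and the one nominally significant row (IPS_DD, p = 0.02 at n = 33)
illustrates exactly why the permutation CI and FDR correction are
reported — the observed difference of 1.6 sits just above the 95% null
interval, a borderline finding one expects occasionally among 24
comparisons. The pinching test shows the built-in device-latency
mechanism: Android models carry ~90–140 ms of extra touch latency,
which at about one pinch per second costs roughly `count × latency`
seconds of the 30 s window (a 100 ms latency over ~30 pinches ≈ 3.08 s
≈ 3 pinches).

The stages can also be run separately (`synth`, `qc`, `features`,
`analyze`), each reading and writing plain CSV/JSON-lines files; see
`equisense --help`.

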