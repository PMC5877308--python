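# Methods

## The problem

Thigh-worn posture trackers report one activity label — sitting, standing,
walking, or idle — per fixed 30-s epoch. Validating such a device against a
reference instrument raises three methodological tasks that this package
implements as a reusable pipeline:

1. **Harmonization.** The reference (direct observation, or an
   inclinometer-style export) is per-second; the device is per-epoch. The
   two streams must be reduced to a common 30-s grid, merged so that only
   periods registered by both remain, and filtered to days with enough
   matched wear time.
2. **Scoring.** Epoch-wise agreement is summarized as one-vs-rest
   sensitivity, specificity, positive predictive rate (PPR, precision) and
   negative predictive rate (NPR) per activity, from a full
   reference × prediction contingency table.
3. **Correction.** When the criterion itself misclassifies, detected
   activity totals can be reallocated using the criterion's misallocation
   profile measured in a calibration sub-study, yielding an estimated
   actual activity distribution.

## Epoch reduction and the tie-break

A 30-s window of per-second labels reduces to the activity performed
longest. Ties among the activity maxima are broken by the fixed priority
sitting > standing > walking (so 8 s sit / 11 s stand / 11 s walk reduces
to standing, and a 10/10/10 three-way split to sitting). This keeps
transition-heavy epochs in the analysis instead of discarding them.

Off/unlabeled seconds are an extension beyond that printed rule: they can
produce an idle epoch only by strict majority over *each* activity, and
idle never wins a tie. Epochs only partially covered by the reference
stream (fewer than 30 recorded seconds) are dropped, mirroring the
exclusion of late-initialization periods at the edges of wear days.
Epochs sit on the absolute UTC 30-s grid (hh:mm:00 / hh:mm:30); device
timestamps are floored to it.

Merging keeps the intersection of epoch starts of the two sources and
records per-source drop counts. The wear filter groups merged epochs by
local calendar day (configurable UTC offset) and retains days with at
least 300 matched minutes; exactly 5 h is retained, "less than 5 h" is
excluded.

## Lab protocols and analysis windows

Three scripted protocol parts are modeled, each with its window rule:

* **Part 1** — six 3-min segments (sit, stand, walk at 80/100/120 bpm, jog
  at 140 bpm) in random order; only the middle minute of each segment is
  analyzed (6 min total).
* **Part 2** — five 2-min segments at the participant's own pace. Variant
  2a analyzes the full 10 min. Variant 2b removes the 30 s before and after
  every *posture-class* change. Pace changes between two walking segments
  (including jogging) are not posture changes; no margin applies before the
  first or after the last segment. Remaining minutes are therefore
  10 − (number of class changes); exhaustive enumeration of all 120
  orderings gives the range 6–8 min. Overlapping margins (only possible
  with nonstandard short segments) are merged.
* **Part 3** — twelve slow sit-down/get-up cycles (1/2/3-s transitions,
  each twice per direction, alternating postures). Each cycle allots 30 s
  for the posture change; exactly the first 30-s epoch of the following
  hold is analyzed (6 min total), even when holds run long.

The 5-s maximum transition is simulator metadata — in synthetic truth the
posture change completes within a uniform 0–5-s delay after the segment
boundary — and does not enter the window arithmetic. Windows are half-open,
30-s aligned, and disjoint by construction.

## Scoring

The contingency table has reference rows {sit, stand, walk} and prediction
columns {sit, stand, walk, idle}; an idle reference label is rejected. In
the one-vs-rest collapse, idle predictions count as false negatives for the
reference activity and as true negatives for every other target — an idle
reading is never a positive detection of anything. Zero-denominator metrics
propagate as explicit `None` markers (rendered `undef.`), never as 0 or
100. Pooled ("all parts") values are computed on summed epoch counts, not
averaged percentages. Reports round to one decimal, half away from zero.

Two decompositions summarize the error structure: per detected activity,
the split of its false positives by actual activity (the misallocation
profile, with denominators = FP epochs), and per actual activity, the split
of its misses by what was predicted instead (denominators = FN epochs,
idle included).

## Reallocation

With detected minutes D_d and a profile {PPR_d, split_d(a)} on the 0–100
scale, the estimated actual minutes of activity a are

    E_a = PPR_a/100 · D_a + Σ_{d≠a} (1 − PPR_d/100) · split_d(a)/100 · D_d.

Internally everything is computed on the 0–1 scale and kept unrounded;
reports round minutes to integers first and divide by wear time second —
the order matters at the printed precision (115.52 min → 116 → 15.0% of
774 min, whereas unrounded division gives 14.9%). When every split sums to
exactly 100%, total minutes are conserved exactly. Split sums tolerate
±0.2 points so profiles published at one-decimal precision (e.g.
33.3 + 66.6) validate.

The profile is a posterior P(actual | detected): it depends on the activity
mix of the data it was measured on. Applying a profile measured under one
mix to data with a different mix biases the estimate — the package applies
it as the method prescribes, and the synthetic end-to-end test keeps
calibration and target arms at the same mix so the recovery property is
tested under the method's own assumption. The estimator is scale-free and
may be applied per day or to per-day means; only mean-level application is
exercised against published-style inputs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
the label level only (no raw accelerations):

* **Free-living days** are alternating bouts of sit/stand/walk. Durations
  are lognormal (σ = 1.0 on the log scale; heavy-tailed sitting bouts are
  the stylized fact in sedentary-behavior research) with mean bouts
  20/8/3 min; the stationary mix defaults to 57/28/15% of wear time and a
  day defaults to 774 wear minutes. Because the process forbids immediate
  self-transitions, next-bout weights are calibrated by a fixed-point
  iteration so the chain's stationary time shares equal the configured mix
  (naive share/mean weights overshoot standing by ~2 points). Single days
  still scatter several points around the mix — heavy tails converge
  slowly — which is realistic between-day variability.
* **Lab sessions** follow a protocol exactly, with posture changes
  completing within 0–5 s after each boundary, so transition-free analysis
  windows contain pure activity by construction.
* **Device observation** reduces truth to grid epochs, corrupts each epoch
  label through a row-stochastic 4×4 confusion matrix, additionally blurs
  epochs that overlap a truth transition (probability 0.5 of reporting a
  uniformly drawn wrong activity — transitions demonstrably degrade
  performance but no rate is published, so this is a modeling choice), and
  drops epochs at rate 0.008 (unexplained device lapses). Two bundled
  error models mimic a high-precision criterion and a consumer test device.
  The expected contingency table is also computed analytically per truth
  epoch, giving the convergence targets for empirical metrics.

All generators are seed-deterministic (numpy `default_rng`; fixture seeds
derived via `SeedSequence.spawn`) and stamp provenance (seed + config
digest) on every fixture.

What passing synthetic tests does **not** show: real devices err in ways no
per-epoch confusion matrix captures (car driving, active sitting,
device-specific filters), real bout structure is subject-specific, and the
reference itself may be imperfect. The generator validates the pipeline's
logic, not any particular device.

## Numerical and interface choices

* Timestamps are integer UNIX seconds (UTC) internally; ISO-8601 in files.
* Labels are case-insensitive on ingest (`off` → idle); unknown strings are
  hard errors with line numbers, never coerced.
* One-hot device exports with all flags false mean idle; more than one true
  flag is a validation error.
* Rounding is half-away-from-zero everywhere a report is printed
  (`Decimal`-based, immune to binary-float `round()` surprises).
* Problem sizes in the statistical tests — 10,000 merged epochs for metric
  convergence, 40 simulated days per arm for the reallocation round-trip,
  60–100 days for mix checks — were chosen as the smallest sizes at which
  the checked tolerances (±2 and ±1.5 points) comfortably exceed sampling
  noise.

## Known limitations

* The wear filter counts merged epochs as wear; it does not re-implement
  proprietary wear-time detection of any commercial software.
* No uncertainty propagation through the reallocation; the estimator
  returns point values only.
* The misallocation profile's mix-dependence (above) means correction with
  a lab-measured profile on free-living data is an approximation; the
  package exposes the machinery but cannot remove that bias.
* Per-second reference files carry no subject id; callers supply one when
  merging against device exports.
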