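# Methods

## The training model

`stilltrain` models operant conditioning of motionlessness as a discrete-time
closed loop between a *subject* (real video feed or simulated animal) and a
*controller*. Time advances in ticks of `read_every_ms` (default 100 ms, the
sampling/recording period). Each tick the controller receives one binary
observation — moved or still — plus any operator commands, and updates:

* the **live still timer**, reset to zero by any sensed movement and by each
  earned reward;
* the **criterion** *c*: the stillness duration currently required for a
  reward. Starting at `set_start_s`, it changes by `auto_delta_s` after every
  `n_periods` *consecutive* earned rewards (any sensed movement resets the
  consecutive count), clamped to the closed interval between `set_start_s`
  and `set_max_s`. With a perfectly still subject and positive step, the
  number of rewards needed to first reach the maximum is exactly
  `n_periods * ceil((set_max_s - set_start_s) / auto_delta_s)`;
* the **drinking window**: for `timeout_s` (default 2 s) after each criterion
  or manual reward, movement is ignored completely — no timer reset, no
  movement count, no red cue — so consuming the reward is never punished;
* the **bonus accumulator**: still time accrued toward `bonus_period_s`; on
  reaching it, a reward of `bonus_multiplier × reward_duration_ms` is issued
  and the accumulator clears. In the default `cumulative` mode the
  accumulator survives movements (it tracks cumulative motionlessness and
  resets only on payout); `bonus_mode = "continuous"` instead clears it on
  every movement. Bonus rewards deliberately do not open a drinking window,
  advance the consecutive-reward count, or touch the still timer — they are
  supplements layered on the main schedule, not part of it.

Cue semantics: flashing green = hold still; solid red = movement sensed this
tick; solid green with red off = drinking window.

### Timing and numerics

All internal timing is integer milliseconds; seconds appear only at the API
and file boundary. Criterion comparisons (`still time ≥ c`) are integer
comparisons, so rewards fire on the first tick at which the criterion is met
and every conservation identity — still + moving + drinking + paused =
elapsed — holds exactly in tick units, not merely to float tolerance.
Identical inputs therefore produce byte-identical logs. A reward emitted by
an operator command occupies that tick's single reward slot; a coinciding
criterion reward (possible only with a zero-length drinking window) fires on
the following tick, within the one-tick quantum the timing contract allows.

### Two stillness clocks

The live timer resets on each reward, but the *longest motionless period*
reported to trainers bridges reward breaks: a subject that holds still
through several criterion cycles, moving only its mouth while drinking, is
credited with one long hold. The controller therefore tracks a separate
bridged still run — broken by sensed movement or a pause, frozen (neither
broken nor extended) during drinking — and the analytics module recomputes
the same quantity independently from the log records. A pause breaks the
run: operator-frozen time is not evidence about the subject.

## Session logs

Records are tab-separated in the fixed column order Elapsed Time (Sec),
Movement, Status, Juice On (mSec), Drink Time (Sec), Time Out (Sec),
Criterion (Sec); seconds print with one decimal (lossless at the default
100 ms tick; finer tick settings should divide 100 ms), valve time as integer
ms. The Movement column records the raw observation even when the controller
ignores it (drinking, paused) — the Status column carries the
interpretation, which is what analytics keys on. Checkpoints are written
atomically (write-new-then-rename) with the column header, so an interrupted
session always leaves a parseable file. The summary block uses `key: value`
lines with full-precision floats, so parsing a finalized log reconstructs
the summary bit-exactly. Encoding is plain ASCII. Timestamps are elapsed
seconds; the wall-clock session start is an optional summary line supplied
by the caller (the CLI records wall time in its run manifest instead, keeping
log bytes reproducible).

`DRINKING` and `TIMEOUT` both name the post-reward window; the controller
writes `DRINKING`, and the parser and analytics accept `TIMEOUT` as a
synonym. `PAUSED` ticks are logged like any other tick.

## Analytics

Percent still time = still time / (elapsed − paused). Still intervals are
maximal runs of still ticks with drinking bridged and movement/pause as
breakers; `best_still_s` is their maximum and `mean_still_interval_s` their
mean ("average cumulative still time" admits two readings, so the mean
interval and the total still time are both reported). Movement counts are
onsets (entries into SENSED MOVE), not moved ticks. Weekly aggregation
buckets sessions into consecutive 7-day windows anchored at the first
session's date and takes per-bucket arithmetic means.

## Motion detection

Absolute per-pixel frame differencing: magnitude = |changed unmasked pixels
where |Δintensity| ≥ `pixel_threshold`| / |unmasked pixels|; moved when
magnitude ≥ `area_fraction`. Defaults `pixel_threshold=15`,
`area_fraction=0.01` suit 8-bit video of a mostly static scene with a
localized moving body part. Masks are unions of half-open, 0-based pixel
rectangles — the convention of surveillance ROI tools and exactly testable.
A mask covering every pixel is rejected (a blind detector is a configuration
error, not an all-still signal). Only the binary moved flag feeds the
controller; magnitude is reported for inspection. `movement_events` merges
movement onsets separated by fewer than `debounce_ticks` still samples.

## The simulated subject and scene

The subject is a two-state renewal process. Idle → moving with per-tick
probability `move_hazard_per_s × dt × learning_factor^(rewards so far)` (a
thinned Bernoulli approximation of a Poisson process, accurate for
hazard × dt ≪ 1); moving → idle with probability `dt / move_duration_s`, so
episode lengths are geometric with the requested mean. Defaults
(hazard 0.05 /s, 0.5 s episodes, no learning) describe a calm restrained
subject; the worked example uses hazard 0.2 /s with `learning_factor=0.95`
to exhibit a within-session learning curve. `drink_motion=True` makes the
subject move during drinking windows, exercising the controller's immunity
rule. One RNG draw is consumed per tick regardless of state, so trajectories
with and without rare events stay aligned under a common seed; all
randomness descends from a single `SeedSequence` split into subject and
scene streams.

The scene renderer emulates the camera view at 64×48 (the detector is
resolution-agnostic; small frames keep rendering fast): uniform background,
optional per-pixel Gaussian noise, and a rectangular blob whose intensity
toggles by `blob_delta` on each moved tick. At zero noise, still pairs are
pixel-identical and moved pairs differ exactly in the blob, making
render→detect an exact inverse pair. What the simulation does **not** model:
lighting drift, camera jitter, partial-body movements of graded size,
satiation, or species-specific behavior — so passing tests demonstrate the
correctness of the control loop and measures, not behavioral realism.

## Problem sizes

The test suite and acceptance script size their simulations for desk-scale
runs: oracle-equivalence uses 1,000 random streams of 10²–10⁴ ticks;
determinism 100 streams; the rate-recovery session runs long enough for
≥500 expected movement onsets (relative sampling error ≈ 3%, comfortably
inside the 10% acceptance band); the showcase session is 30 simulated
minutes, matching a typical early training session's length.

## Known limitations

* The log's one-decimal elapsed column quantizes away sub-0.1 s ticks; use
  tick periods that are multiples of 100 ms when logs must round-trip.
* Continuous (operator-held) rewards open no drinking window; the operator
  is presumed to manage the subject during manual intervention.
* The criterion column in records is printed at 0.1 s precision; schedules
  using finer steps survive in memory but not through a log round trip.
* Weekly aggregation needs session dates; undated sessions appear in
  per-session rows but not weekly means.
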