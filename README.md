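# stilltrain

A software-only re-creation of an automated operant-conditioning system for
training restrained laboratory animals (e.g. head-fixed macaques prepared for
awake PET/fMRI) to remain motionless for long periods. The original class of
system couples a surveillance camera to a control program that flashes a
green "hold still" cue, lights a red cue when movement is sensed, dispenses a
liquid reward after every criterion interval of stillness, and logs every
sampling tick. `stilltrain` implements that entire loop as testable software:
no camera, valve, or animal required.

## What it does

* **Motion detection** (`stilltrain.motion`) — frame differencing over
  grayscale image sequences with rectangular exclusion masks: motion is
  declared when the fraction of unmasked pixels whose intensity changes by at
  least `pixel_threshold` reaches `area_fraction`.
* **Controller** (`stilltrain.controller`) — a deterministic discrete-time
  state machine (statuses START, STILL, SENSED MOVE, REWARD, MANUAL,
  DRINKING, TIMEOUT, PAUSED). Movement resets the reward-interval timer; a
  criterion interval *c* of uninterrupted stillness earns a reward; a 2 s
  post-reward drinking window ignores movement entirely so drinking is never
  punished. The criterion adapts: after every `n_periods` consecutive earned
  rewards it moves by `auto_delta_s`, clamped between `set_start_s` and
  `set_max_s`. Accumulated stillness also earns larger *bonus* rewards.
* **Session log** (`stilltrain.session_log`) — the per-tick ASCII log
  (Elapsed Time, Movement, Status, Juice On, Drink Time, Time Out,
  Criterion), crash-safe checkpointing, and the end-of-session summary block
  (percent still time, rewards given, duration, longest motionless period,
  start/end criteria) prepended to the file.
* **Analytics** (`stilltrain.analytics`) — training-progress measures from
  logs: best motionless period (drinking pauses *bridged*, so reward breaks
  do not cut a hold short), percent still time, movement counts, mean still
  interval, and weekly averages across sessions.
* **Simulation** (`stilltrain.simulate`) — a stochastic subject (idle/moving
  renewal process with optional reward-contingent hazard decay) run closed
  loop against the controller, plus a synthetic scene renderer whose output
  the detector inverts exactly at zero noise.

## Worked example

Simulate a 30-minute session with a learning subject (movement hazard
0.2 /s, decaying 5% per reward) under the standard schedule (5 s start,
+5 s per 2 consecutive rewards, 95 s max, 2 s drinking window):

```bash
$ stilltrain simulate --config examples/config.toml --duration 1800 --seed 7 --log demo.log
simulated 1800.0 s: 66 rewards, 93.2% still, criterion 5 -> 55 s
$ head -8 demo.log
Animal ID: m1
Experimenter: trainer
Duration (Sec): 1800.0
Percent Still: 0.9321111111111111
Rewards Given: 66
Longest Still (Sec): 212.7
Start Criterion (Sec): 5.0
End Criterion (Sec): 55.0
```

The subject held still 93.2% of the session, earned 66 rewards, and worked
its way from a 5 s criterion up to 55 s; its longest motionless period
(bridging the 2 s drinking breaks) was 212.7 s. Then:

```bash
$ stilltrain log validate demo.log     # recompute the summary from the records
demo.log: OK (18000 records, summary consistent)
$ stilltrain analyze demo.log --out report.csv
```

Other subcommands: `stilltrain detect` (frame-difference a PGM sequence into
a motion-sample TSV), `stilltrain train` (replay a recorded sample/command
stream through the controller), and `--frames-out` on `simulate` to render
the synthetic camera view.

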