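# Methods

## Scope and model of the system

`cagetrain` simulates an automated operant-training stack as a
discrete-event system with four layers:

1. an FSM **engine** executing one trial machine (or several
   concurrently) against a timestamped event stream;
2. a **trainer** holding each subject's position in a shaping protocol
   and supplying the engine with the current stage's machine;
3. a **scheduler** opening nightly training and free-water sessions and
   settling water ledgers;
4. **virtual subjects** converting task state into input events.

Everything hardware-bound in the real system (DAQ, valves, video,
multi-computer deployment) is out of scope; the valve is represented by
its dispensed-volume equivalent (0.0002 ml per ms of open time, i.e.
0.04 ml for a 200 ms pulse).

## Trial engine

Trial machines are declarative: states with entry/exit actions and
transitions triggered by event predicates (channel, optional value
condition, optional time-in-state gate) or by timeouts.  Numerical and
semantic choices:

- **Clock.** A virtual discrete-event clock; timestamps are carried in
  microseconds, decisions are made at 1 ms resolution.  All task
  constants (100, 700, 1200, 3000, 7000 ms) are far above this
  resolution.  There is no real-time mode.
- **Dispatch.** Among rules of one source state that match an event, the
  lowest integer priority fires; equal priorities on a shared source are
  a validation error, so dispatch is total and deterministic.
- **Timeouts vs events.** A timeout whose deadline is ≤ the next event's
  timestamp fires first (ties go to the timeout).  Exit actions fire on
  timeout-triggered transitions exactly as on event-triggered ones; the
  alternative (suppressing exit actions on timeouts) has no observable
  consequence in the shipped tasks but the symmetric rule is simpler to
  reason about.
- **Non-matching events** are consumed into the trial's event trace
  without changing state — this is what makes the lever task's lockout
  "ignore" presses.
- **Degenerate machines.** Validation rejects unreachable terminals,
  dangling endpoints, duplicate priorities and dead-end states, but a
  *valid* machine can still cycle through timeout edges forever once the
  event stream is exhausted; `run_concurrent` therefore carries a
  transition budget (default 10⁶) and raises rather than spin.
- An exhausted event source with no pending timeout yields the outcome
  `aborted`.
- **Joystick geometry.** Joystick events carry `(segment,
  displacement_cm)`; threshold crossings are decided by transition
  predicates, not by the event source, so the same event stream can be
  replayed through machines with different thresholds.

Determinism: the engine contains no randomness, so identical (machine,
event stream) give bit-identical records; this is asserted by replay
tests and an independent table-driven reference interpreter.

## Shaping protocols

A criterion is a metric (`fraction-rewarded`, `count-rewarded`,
`fraction-correct`) over the last *window* trials, evaluable only after
*min_trials* trials in the current stage, checked after **every** trial
(not per session — the simplest semantics consistent with continuous
performance monitoring).  The default criterion is fraction-rewarded
≥ 0.7 over the last 30 trials.  Stages never demote; stalled subjects
are a reporting flag (no advancement within a wall-clock budget), not a
protocol mechanism.  Stage history is cleared on promotion, so each
stage is judged on its own trials.

The center-out ladder ships with stage 2 ramping the required downward
displacement through 0.5/1.0/1.5/2.0 cm and stage 3 ramping the lateral
displacement through 1–5 cm.  These counts and increments are package
defaults chosen to be plausible shaping steps; they are configuration,
not a claim about any particular laboratory's ladder.

## Scheduling and water accounting

The subjective night is a 12 h window; all windows must fit inside it.
Defaults follow the six-session structure (30 min every 2 h) with one
free-water settlement window after the last session and a rest night
every 7th night.  Session-start cues are house-light blinks, a 10 s
1 kHz tone and 3 × 0.01 ml priming drops (volume is a package default —
only "a few drops" is specified anywhere — and counts toward earned
water).  Dispensing is lick-gated everywhere, including the free-water
top-up (modeled as lick-gated 0.05 ml aliquots) and rest-day ad libitum
water.  The settlement rule is `max(0, 0.05 ml/g × body weight −
earned)`; body weight is a per-subject constant.  The watchdog flags
components silent beyond a heartbeat timeout (default 2 min) and
linearly projects intake to end of night for an early low-water warning;
the settlement still enforces the floor regardless.

## Tasks

**Lever task.** Reward iff the inter-press interval lies in the closed
window `[700 − h, 700 + h]` ms.  The controller recomputes the rewarded
fraction over the last N = 50 trials after every trial: above 0.40 it
multiplies *h* by 0.95, below 0.30 by 1.05, clamped to h ∈ [20, 700] ms,
starting at h = 700 (everything rewarded at first, so shaping proceeds
from success).  With fewer than 50 trials of history the window is left
unchanged.  For a stationary Normal(μ = 700, σ = 150) presser the
controller equilibrates where 2Φ(h/σ) − 1 crosses the band, i.e.
h ≈ 60–80 ms, with multiplicative hunting around it; the measured
rewarded fraction over the last 2,000 of 20,000 trials sits inside the
30–40% band.  The *analysis* metric ("correct" trials) is fixed at ±30%
of the 700 ms target ([490, 910] ms) and is independent of the reward
window in force.

**Center-out.** Initiation threshold ≥ 2 cm (inclusive, "~2 cm");
lateral target strictly > 5 cm (as printed); wrong-arm crossings enter a
7 s penalty state ending in an error terminal; the cued side is drawn
uniformly per trial.

**Sequence task.** Guided phase until 2 consecutive correct (hard cap 10
guided trials to keep blocks finite); memory phase until 2 consecutive
correct (completed) or 10 memory-guided trials (incomplete).  The
10-trial budget applies to **memory-guided trials only** — this is the
package's main interpretive commitment, made because the reported trial
counts "range from 2 to 10" refer to memory-guided trials; the
alternative reading (guided + memory ≤ 10) is available via
`SequenceTaskConfig(budget_includes_guided=True)`.  An erroneous
movement ends its trial immediately; the recorded movement string is
truncated at the first error.  Incomplete blocks are *scored* at the
full budget of 10 memory trials, so the unconditional mean (reported
beside the conditional mean) counts them at 10.

## Virtual subjects

Agents are deterministic functions of (parameters, seed, call history);
all randomness flows through a numpy Generator seeded from the
experiment seed via `SeedSequence.spawn`.

- *chance*: follows cues exactly on guided trials (so chance affects
  only the memory phase, and chance blocks always enter it after exactly
  2 guided trials) and draws uniform L/R movements on memory trials.
- *bernoulli(p)*: succeeds on a memory trial with probability p; used to
  probe the chance analytics over a (p, n) grid through the same task
  code path.
- *learning*: success probability p(t) = p∞ − (p∞ − p0)·exp(−t/τ) — the
  simplest monotone saturating curve; it exists to exercise the trainer,
  not as a model of rats.
- *timing*: IPIs from Normal(μ, σ) truncated at 0 (rejection sampling;
  for μ ≫ σ the truncation is negligible, and σ = 0 returns μ exactly).
- *perfect*/*never*/*scripted* (JSONL replay) for oracles and plumbing.

Licking follows every reward tone with probability 1 by default, so
water ledgers are deterministic in tests.

What the generator does **not** emulate: motor kinematics (only
threshold crossings), circadian motivation, satiety, inter-animal
variability in engagement, or any learning dynamics beyond the
saturating curve.  Passing tests therefore validate the *control stack
and its statistics*, not predictions about animal behavior; published
animal-derived values (e.g. a 63% completion fraction, 3.2 memory
trials, a 24× in/out-session ratio) are benchmarks the real animals
produced and are deliberately not simulation targets.

## Chance model

The closed form uses the no-run recurrence a₀ = a₁ = 1,
aₖ = (1−p)aₖ₋₁ + p(1−p)aₖ₋₂ (aₖ = probability of no 2 consecutive
successes in k trials); completion within budget n is 1 − aₙ and the
first-completion mass is f(2) = p², f(k) = aₖ₋₃(1−p)p² for k ≥ 3.  For
p = 0.25, n = 10 this gives completion 0.388199 and conditional mean
5.5557, verified exactly (to 1e−12) against exhaustive enumeration of
all success/failure strings for n ≤ 12.  The Monte-Carlo route runs the
real block machinery with the chance agent and agrees within 3 SE at
10⁵ blocks across p ∈ {0.1, 0.25, 0.5, 0.9}, n ∈ {4, 10, 20}.

A widely quoted chance level for the conditional mean is 5.4, slightly
below the 5.56 this budget semantics yields analytically; the original
simulation protocol behind 5.4 (per-animal block counts, exact budget
accounting) is not specified anywhere we can check, so the discrepancy
is documented here rather than tuned away, and both budget semantics are
switchable.  Confidence intervals: normal approximation for the
completion fraction; seeded percentile bootstrap (1,000 resamples) for
the conditional mean.  Chance-comparison tail probabilities are computed
by Monte-Carlo tail counts with matched block counts and are reported,
never gated on.

## Problem sizes and numerical choices

The shipped analyses use 10⁵ chance blocks (completion-fraction SE
≈ 0.0015) and 20,000 lever trials with the last 2,000 scored — sizes at
which all Monte-Carlo checks resolve their targets at 3 SE while a full
test run stays in the minutes range on one CPU.  Colony simulations in
tests use short sessions (minutes) and small colonies; the runner's
virtual trial pacing (≈ 2 s inter-trial interval, 5 s per sequence
trial) only sets how many trials fit in a session, not any statistic's
value.  Ties, boundaries and degenerate inputs: the lever window is
closed at both ends; the correct-trial band [490, 910] ms is closed;
p = 0 makes the conditional mean NaN; zero-variance columns yield NaN
correlations; an all-in-session event stream yields an infinite
in/out ratio by convention.

## Known limitations

- No hierarchical states or real-time execution; plugin behavior is
  reduced to named action hooks.
- The event store is single-process SQLite; concurrent writers are out
  of scope.
- Sequence lengths other than 2 are accepted by configuration but not
  validated by the shipped analytics.
- The center-out sub-stage ladder and the per-reward volume (0.04 ml)
  are package defaults, not published constants.
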