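# cagetrain

A desk-scale, hardware-free simulator of fully automated home-cage
operant training for rodents.  It reimplements the full control stack of
an automated training system — finite-state-machine (FSM) trial control,
criterion-driven shaping protocols, nightly session scheduling with
water-restriction accounting, and safety supervision — and replaces the
animal and the I/O hardware with seedable virtual subjects, so that
training protocols and their analytics can be developed, tested and
benchmarked entirely at a desk.

It is aimed at behavioral neuroscientists and engineers who design
automated operant-conditioning experiments and want to validate trial
logic, shaping ladders, reward contingencies and chance models before
any animal is involved.

## What it implements

**Trial control.** Each behavioral trial is a declarative FSM: states
carry entry/exit actions (LEDs, tones, valve pulses), and transitions
fire on input events (lever presses, licks, joystick threshold
crossings) or on timeouts.  The engine validates machines, executes them
— alone or concurrently over one shared event stream — against a
virtual 1 ms-resolution clock, and returns fully timestamped trial
records.  Execution is deterministic: identical (machine, event stream)
give bit-identical records.

**Shaping protocols.** A protocol is an ordered ladder of (stage,
sub-stage) entries, each pairing an FSM builder with an advancement
criterion over recent trial outcomes (e.g. fraction rewarded ≥ 0.7 over
the last 30 trials).  The trainer evaluates the criterion after every
trial and only ever advances.

**Scheduling and safety.** Training runs in short sessions through the
subject's 12 h subjective night (default: six 30-minute sessions every
2 h), each opened by a cue sequence (blinking house lights, a 10 s
1 kHz tone, priming water drops).  Water is dispensed only upon licking
the reward spout; at end of night every subject is topped up to the
daily minimum of 5 ml per 100 g body weight, and a watchdog monitors
component heartbeats and projected intake.

**Benchmark tasks.**

- *Center-out joystick*: initiate by moving the joystick ~2 cm down an
  inverted-Y slit, then >5 cm along the cued arm; wrong-direction
  movements incur a 7 s timeout.  Shipped as a 3-stage shaping ladder.
- *Precise lever pressing*: two presses separated by 700 ms, rewarded
  when the inter-press interval (IPI) falls inside a symmetric window
  whose half-width *h* is servoed multiplicatively (shrink ×0.95 above
  40% rewarded, expand ×1.05 below 30%, over the last 50 trials) so the
  steady-state reward rate sits in the 30–40% band; misses impose a
  1.2 s lockout.
- *Memory-guided sequences*: blocks of a fixed 2-movement left/right
  sequence, visually guided until 2 consecutive correct, then performed
  from memory; 2 consecutive correct memory-guided trials complete the
  block, a 10-trial memory budget ends it incomplete.

**Chance model.** For the sequence task, chance behavior is random L/R
movements on memory-guided trials, so each trial succeeds with
p = 0.25.  Writing aₖ for the probability that k Bernoulli(p) trials
contain no run of 2 successes,

    a₀ = a₁ = 1,  aₖ = (1−p)·aₖ₋₁ + p(1−p)·aₖ₋₂,

the block-completion probability within budget n is 1 − aₙ, and the
first-completion mass is f(2) = p², f(k) = aₖ₋₃(1−p)p² for k ≥ 3.  Both
this closed form and a Monte-Carlo route through the actual task
machinery are provided and cross-checked.

## Worked example

```python
from cagetrain.analytics import analytic_chance, simulate_chance
from cagetrain.tasks import SequenceTaskConfig

exact_completion, exact_mean = analytic_chance(p=0.25, n=10)
mc = simulate_chance(SequenceTaskConfig(), n_blocks=100_000, seed=2024)
print(f"analytic : completion {exact_completion:.4f}, mean memory trials {exact_mean:.3f}")
print(f"simulated: completion {mc.completion_fraction:.4f}, "
      f"mean memory trials {mc.mean_memory_trials_completed:.3f}")
```

prints

```
analytic : completion 0.3882, mean memory trials 5.556
simulated: completion 0.3895, mean memory trials 5.567
```

i.e. a purely random subject completes ≈ 39% of sequence blocks, using
≈ 5.6 memory-guided trials in the blocks it does complete — the chance
floor against which trained performance is judged.  The same numbers
fall out of the full pipeline (`cagetrain run` on a chance-agent
colony), which is how the package validates its own trial engine.

The CLI wraps the same machinery:

```
cagetrain chance --blocks 100000 --seed 2024
cagetrain validate --config experiment.yaml
cagetrain run --config experiment.yaml --out results/
cagetrain stats --trials results/trials.csv
```

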