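"""Performance statistics and the chance model of the sequence task.

The chance model treats every memory-guided trial as two independent
fair left/right draws scored against the block's fixed 2-movement
target, so each trial succeeds with probability p = 0.25.  A block
completes when 2 consecutive successes occur within the memory-trial
budget (10 by default).  Both a Monte-Carlo implementation (driving the
actual task machinery with a chance agent) and a closed-form recurrence
are provided and cross-checked.

The recurrence counts sequences with no success-run of length 2:
``a_0 = a_1 = 1``, ``a_k = (1-p) a_{k-1} + p (1-p) a_{k-2}``; the
completion probability within budget n is ``1 - a_n`` and the
first-completion mass is ``f(2) = p^2``, ``f(k) = a_{k-3} (1-p) p^2``
for k >= 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .agents import AgentPolicy, VirtualSubject
from .tasks import SequenceTaskConfig, draw_next_sequence, run_sequence_block

__all__ = [
    "ChanceModelResult",
    "PerformanceSummary",
    "analytic_chance",
    "simulate_chance",
    "correct_fraction",
    "in_out_session_ratio",
    "stage_time_correlations",
    "completion_tail_probability",
]


@dataclass(frozen=True)
class ChanceModelResult:
    """Monte-Carlo chance-model summary for the sequence task."""

    p_correct: float
    budget: int
    n_blocks: int
    completion_fraction: float
    completion_ci: Tuple[float, float]
    mean_memory_trials_completed: float  # conditional on completion
    mean_memory_trials_ci: Tuple[float, float]
    mean_memory_trials_all: float  # incomplete blocks counted at budget
    seed: Optional[int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.completion_fraction <= 1.0):
            raise ValueError("completion fraction out of [0, 1]")


@dataclass(frozen=True)
class PerformanceSummary:
    """Aggregate task performance over a simulated subject or colony."""

    fraction_correct: float
    trials_per_day: float
    fraction_completed_blocks: Optional[float] = None
    mean_memory_trials: Optional[float] = None
    in_out_ratio: Optional[float] = None


def analytic_chance(p: float, n: int) -> Tuple[float, float]:
    """Completion probability and conditional mean trials, in closed form.

    ``p`` is the per-trial success probability, ``n`` the memory-trial
    budget.  Returns ``(P(complete within n), E[trials | complete])``;
    the conditional mean is NaN when completion is impossible (p = 0).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if n < 2:
        raise ValueError("budget must be at least 2 trials")
    # a[k] = P(no run of 2 consecutive successes in k trials)
    a = [1.0, 1.0]
    for k in range(2, n + 1):
        a.append((1 - p) * a[k - 1] + p * (1 - p) * a[k - 2])
    completion = 1.0 - a[n]
    if completion == 0.0:
        return 0.0, math.nan
    mass = {2: p * p}
    for k in range(3, n + 1):
        mass[k] = a[k - 3] * (1 - p) * p * p
    cond_mean = sum(k * f for k, f in mass.items()) / completion
    return completion, cond_mean


def simulate_chance(
    config: Optional[SequenceTaskConfig] = None,
    n_blocks: int = 100_000,
    seed: Optional[int] = 0,
    p_success: Optional[float] = None,
    n_bootstrap: int = 1000,
) -> ChanceModelResult:
    """Monte-Carlo chance model: run the sequence task with a chance agent.

    Each block draws a fresh target sequence and runs
    :func:`~cagetrain.tasks.run_sequence_block` with an agent that
    follows cues on guided trials and moves at random on memory-guided
    trials.  ``p_success`` switches to a Bernoulli agent with that
    per-trial success probability (for probing the analytics on a
    (p, n) grid).  95% CIs: normal approximation for the completion
    fraction, seeded percentile bootstrap for the conditional mean.
    """
    config = config or SequenceTaskConfig()
    if n_blocks < 1:
        raise ValueError("need at least one block")
    root = np.random.SeedSequence(seed)
    rng_seq, rng_agent, rng_boot = (np.random.default_rng(s) for s in root.spawn(3))
    if p_success is None:
        policy = AgentPolicy("chance")
        p_eff = (1.0 / len(config.alphabet)) ** config.sequence_length
    else:
        policy = AgentPolicy("bernoulli", {"p": p_success})
        p_eff = p_success
    subject = VirtualSubject(policy, rng_agent)

    completed = np.empty(n_blocks, dtype=bool)
    mem_trials = np.empty(n_blocks, dtype=np.int64)
    for i in range(n_blocks):
        target = draw_next_sequence(rng_seq, config)
        block = run_sequence_block(target, subject, config, block_index=i)
        completed[i] = block.completed
        mem_trials[i] = block.n_memory_trials

    frac = float(completed.mean())
    se = math.sqrt(max(frac * (1 - frac), 1e-12) / n_blocks)
    ci = (frac - 1.96 * se, frac + 1.96 * se)

    done = mem_trials[completed]
    if done.size:
        cond_mean = float(done.mean())
        if n_bootstrap > 0 and done.size > 1:
            boots = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                idx = rng_boot.integers(0, done.size, size=done.size)
                boots[b] = done[idx].mean()
            mean_ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        else:
            mean_ci = (cond_mean, cond_mean)
    else:
        cond_mean = math.nan
        mean_ci = (math.nan, math.nan)

    return ChanceModelResult(
        p_correct=p_eff,
        budget=config.trial_budget,
        n_blocks=n_blocks,
        completion_fraction=frac,
        completion_ci=ci,
        mean_memory_trials_completed=cond_mean,
        mean_memory_trials_ci=mean_ci,
        mean_memory_trials_all=float(mem_trials.mean()),
        seed=seed,
    )


def completion_tail_probability(
    observed_fraction: float,
    n_blocks: int,
    p: float = 0.25,
    budget: int = 10,
    n_sims: int = 100_000,
    seed: Optional[int] = 0,
) -> float:
    """Monte-Carlo tail probability of observing a completion fraction at
    least as large as ``observed_fraction`` by chance, over a matched
    number of blocks (reported alongside chance comparisons, not gated)."""
    completion, _ = analytic_chance(p, budget)
    rng = np.random.default_rng(seed)
    sims = rng.binomial(n_blocks, completion, size=n_sims) / n_blocks
    return float((sims >= observed_fraction).mean())


def correct_fraction(
    ipis_ms: Sequence[float],
    target_ms: float = 700.0,
    band: float = 0.30,
) -> float:
    """Fraction of trials whose inter-press interval lies within ``band``
    (30% by default) of the target — the analysis metric, independent of
    the adaptive reward window in force at the time."""
    arr = np.asarray(ipis_ms, dtype=float)
    if arr.size == 0:
        raise ValueError("no trials supplied")
    lo, hi = target_ms * (1 - band), target_ms * (1 + band)
    return float(((arr >= lo) & (arr <= hi)).mean())


def in_out_session_ratio(
    event_minutes: Sequence[float],
    schedules: Sequence,
    night_minutes: float = 24 * 60,
) -> float:
    """Ratio of in-session to out-of-session manipulandum event rates.

    ``event_minutes`` are event times in minutes from the start of night
    0; night k occupies ``[k * night_minutes, (k+1) * night_minutes)``
    and each schedule's windows are offsets into its night.  Returns
    ``inf`` when all events fall in-session; raises on zero-duration
    denominators.
    """
    events = np.asarray(event_minutes, dtype=float)
    intervals = []
    for sched in schedules:
        base = sched.night_index * night_minutes
        for w in sched.windows:
            if w.kind == "training":
                intervals.append((base + w.start_min, base + w.end_min))
    in_minutes = sum(e - s for s, e in intervals)
    total_minutes = len(schedules) * night_minutes
    out_minutes = total_minutes - in_minutes
    if in_minutes <= 0 or out_minutes <= 0:
        raise ValueError("schedule leaves a zero-duration in- or out-of-session span")
    in_mask = np.zeros(events.shape, dtype=bool)
    for s, e in intervals:
        in_mask |= (events >= s) & (events < e)
    in_rate = in_mask.sum() / in_minutes
    out_rate = (~in_mask).sum() / out_minutes
    if out_rate == 0:
        return math.inf
    return float(in_rate / out_rate)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from the defining formula."""
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float((xd * xd).sum()) * float((yd * yd).sum()))
    if denom == 0.0:
        return math.nan
    return float((xd * yd).sum() / denom)


def stage_time_correlations(times) -> dict:
    """Pairwise Pearson correlations between per-subject stage durations.

    ``times`` is an (n_subjects, n_stages) array of completion
    durations; requires at least 3 subjects and no missing values.
    Returns ``{(i, j): r}`` over stage pairs (0-based); a pair with a
    zero-variance column yields NaN.
    """
    arr = np.asarray(times, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need a 2D array with at least 3 subjects")
    if np.isnan(arr).any():
        raise ValueError("missing stage durations")
    n_stages = arr.shape[1]
    return {
        (i, j): _pearson(arr[:, i], arr[:, j])
        for i in range(n_stages)
        for j in range(i + 1, n_stages)
    }
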