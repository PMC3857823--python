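"""Virtual subjects: seedable agents standing in for the animal.

Agents translate task state (cues, reward tones) into input events —
lever presses, licks, joystick movements — so the whole training stack
runs without hardware or animals.  Variants:

``chance``
    The chance model of the sequence task: follows cues exactly on
    visually guided trials, makes uniform random left/right movements
    on memory-guided trials.
``bernoulli``
    Succeeds on a memory-guided trial with fixed probability ``p``
    (used to probe the chance analytics on a (p, n) grid).
``learning``
    Per-trial success probability rises along a saturating curve
    p(t) = p_inf - (p_inf - p0) * exp(-t / tau).
``timing``
    Emits inter-press intervals from a truncated Normal(mu, sigma).
``perfect`` / ``never``
    Always / never produce the correct response.
``scripted``
    Replays a pre-recorded JSONL event stream.

All agents are deterministic functions of (parameters, seed, history).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fsm import InputEvent

__all__ = [
    "AgentPolicy",
    "LearningCurve",
    "TimingModel",
    "VirtualSubject",
    "chance_move",
    "sample_ipi",
    "respond",
    "load_scripted_events",
]

VARIANTS = ("chance", "bernoulli", "learning", "timing", "scripted", "perfect", "never")


@dataclass(frozen=True)
class LearningCurve:
    """Saturating success curve p(t) = p_inf - (p_inf - p0) exp(-t/tau)."""

    p0: float = 0.1
    p_inf: float = 0.9
    tau: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= self.p_inf <= 1.0):
            raise ValueError("require 0 <= p0 <= p_inf <= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def p(self, trial_index: int) -> float:
        return self.p_inf - (self.p_inf - self.p0) * float(np.exp(-trial_index / self.tau))


@dataclass(frozen=True)
class TimingModel:
    """Inter-press-interval model: Normal(mu, sigma) truncated at 0 ms.

    ``drift_per_trial`` optionally moves mu toward ``drift_target_ms``
    each trial, emulating gradual timing improvement.
    """

    mu_ms: float = 700.0
    sigma_ms: float = 150.0
    drift_per_trial: float = 0.0
    drift_target_ms: float = 700.0

    def __post_init__(self) -> None:
        if self.sigma_ms < 0:
            raise ValueError("sigma must be >= 0")

    def mu_at(self, trial_index: int) -> float:
        if self.drift_per_trial == 0.0:
            return self.mu_ms
        shift = 1.0 - (1.0 - self.drift_per_trial) ** trial_index
        return self.mu_ms + (self.drift_target_ms - self.mu_ms) * shift


@dataclass(frozen=True)
class AgentPolicy:
    """Declarative agent description: variant, parameters, seed."""

    variant: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown agent variant {self.variant!r}")
        p = self.params.get("p")
        if p is not None and not (0.0 <= p <= 1.0):
            raise ValueError("probability parameter must lie in [0, 1]")


def chance_move(rng: np.random.Generator) -> str:
    """One uniform random left/right movement: 'L' or 'R', p = 0.5 each."""
    return "L" if rng.random() < 0.5 else "R"


def sample_ipi(model: TimingModel, rng: np.random.Generator, trial_index: int = 0) -> float:
    """Draw a positive inter-press interval (ms) from the truncated normal."""
    mu = model.mu_at(trial_index)
    if model.sigma_ms == 0.0:
        return mu
    while True:
        x = rng.normal(mu, model.sigma_ms)
        if x > 0:
            return float(x)


def load_scripted_events(path) -> list:
    """Read a replay stream: JSONL, one InputEvent per line."""
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(InputEvent.from_dict(json.loads(line)))
    return events


def _flip(move: str) -> str:
    return "R" if move == "L" else "L"


class VirtualSubject:
    """Stateful runtime wrapper around an :class:`AgentPolicy`.

    Keeps the agent's own random generator and trial counter so that
    identical (policy, seed, call history) yield identical behavior.
    """

    def __init__(self, policy: AgentPolicy, rng: Optional[np.random.Generator] = None):
        self.policy = policy
        self.rng = rng if rng is not None else np.random.default_rng(policy.seed)
        self.trials_seen = 0
        self.lick_probability = float(policy.params.get("lick_probability", 1.0))
        if policy.variant == "learning":
            self.curve = LearningCurve(
                p0=policy.params.get("p0", 0.1),
                p_inf=policy.params.get("p_inf", 0.9),
                tau=policy.params.get("tau", 200.0),
            )
        if policy.variant == "timing":
            self.timing = TimingModel(
                mu_ms=policy.params.get("mu_ms", 700.0),
                sigma_ms=policy.params.get("sigma_ms", 150.0),
                drift_per_trial=policy.params.get("drift_per_trial", 0.0),
                drift_target_ms=policy.params.get("drift_target_ms", 700.0),
            )
        if policy.variant == "scripted":
            self._script = list(policy.params.get("events", []))

    # --- sequence / center-out responses ------------------------------

    def _succeeds(self) -> bool:
        v = self.policy.variant
        if v == "perfect":
            return True
        if v == "never":
            return False
        if v == "bernoulli":
            return bool(self.rng.random() < self.policy.params.get("p", 0.25))
        if v == "learning":
            return bool(self.rng.random() < self.curve.p(self.trials_seen))
        raise ValueError(f"variant {v!r} has no success model")

    def sequence_movements(self, target: Sequence[str], guided: bool) -> list:
        """Movement pair produced on one sequence-task trial.

        The chance model follows the cues exactly when they are shown
        (guided trials) and draws uniform random movements when they are
        not (memory-guided trials).
        """
        self.trials_seen += 1
        v = self.policy.variant
        if v == "chance":
            if guided:
                return list(target)
            return [chance_move(self.rng) for _ in target]
        if v in ("bernoulli", "learning"):
            if guided:
                return list(target)
            if self._succeeds():
                return list(target)
            # flip one movement so the trial is wrong by construction
            idx = int(self.rng.integers(len(target)))
            wrong = list(target)
            wrong[idx] = _flip(target[idx])
            return wrong
        if v == "perfect":
            return list(target)
        if v == "never":
            return [_flip(target[0])] + list(target[1:])
        raise ValueError(f"variant {v!r} cannot do the sequence task")

    def center_out_succeeds(self) -> bool:
        """Whether the agent makes the cued center-out movement correctly."""
        self.trials_seen += 1
        if self.policy.variant == "chance":
            return bool(self.rng.random() < 0.5)
        return self._succeeds()

    # --- lever-task responses ------------------------------------------

    def next_ipi_ms(self) -> float:
        if self.policy.variant == "perfect":
            self.trials_seen += 1
            return 700.0
        if self.policy.variant != "timing":
            raise ValueError("inter-press intervals require a timing (or perfect) agent")
        ipi = sample_ipi(self.timing, self.rng, self.trials_seen)
        self.trials_seen += 1
        return ipi

    def licks(self) -> bool:
        """Whether the agent licks the spout after a reward tone."""
        if self.lick_probability >= 1.0:
            return True
        return bool(self.rng.random() < self.lick_probability)


def respond(
    subject: VirtualSubject,
    context: dict,
    t_start_us: int = 0,
) -> list:
    """Produce the event-stream fragment for one trial.

    ``context`` identifies the task and its cue state:

    - ``{"task": "lever", ...}``: two presses separated by the agent's
      inter-press interval, then a lick (reward collection attempt).
    - ``{"task": "sequence", "target": "LR", "guided": bool}``: joystick
      initiation then the agent's two movements, then a lick.
    - ``{"task": "center_out", "cue": "L"|"R", "down_cm": d,
      "lateral_cm": l}``: downward initiation then a full-excursion
      movement along the chosen arm, then a lick.

    Scripted agents ignore the context and replay their recorded stream.
    """
    if subject.policy.variant == "scripted":
        return [e for e in subject._script if e.t_us >= t_start_us]

    task = context.get("task")
    t = t_start_us
    events: list = []
    if task == "lever":
        ipi_ms = subject.next_ipi_ms()
        events.append(InputEvent("lever", 1, t))
        t += int(round(ipi_ms * 1000))
        events.append(InputEvent("lever", 1, t))
        if subject.licks():
            events.append(InputEvent("lick", 1, t + 50_000))
        return events
    if task == "sequence":
        target = list(context["target"])
        guided = bool(context.get("guided", True))
        moves = subject.sequence_movements(target, guided)
        events.append(InputEvent("joystick", ("DOWN", 2.5), t))
        for i, m in enumerate(moves):
            seg = "LEFT" if m == "L" else "RIGHT"
            t += 300_000
            events.append(InputEvent("joystick", (seg, 5.5), t))
        if subject.licks():
            events.append(InputEvent("lick", 1, t + 50_000))
        return events
    if task == "center_out":
        ok = subject.center_out_succeeds()
        cue = context.get("cue", "L")
        move = cue if ok else _flip(cue)
        seg = "LEFT" if move == "L" else "RIGHT"
        down = float(context.get("down_cm", 2.0))
        lateral = float(context.get("lateral_cm", 5.0))
        events.append(InputEvent("joystick", ("DOWN", down + 0.1), t))
        events.append(InputEvent("joystick", (seg, lateral + 0.1), t + 300_000))
        if subject.licks():
            events.append(InputEvent("lick", 1, t + 400_000))
        return events
    raise ValueError(f"unknown task context {task!r}")
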