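"""Builders for the three benchmark tasks.

* **Center-out joystick**: move a 2D joystick down an inverted-Y slit to
  initiate (~2 cm), then >5 cm along the cued arm for a reward tone
  (1000 Hz, 100 ms) and lick-gated water; a wrong-direction movement
  triggers a 7 s timeout.  Shaped in three stages with sub-stage ramps.
* **Precise lever pressing**: two presses separated by 700 ms; rewarded
  when the inter-press interval falls inside an adaptive symmetric
  window whose half-width is servoed to keep ~30-40% of trials
  rewarded; misses impose a 1.2 s lockout before re-initiation.
* **Memory-guided sequences**: blocks of 2-movement left/right sequences;
  visually guided until 2 consecutive correct, then cues are removed and
  the sequence must be produced from memory — 2 consecutive correct
  memory trials complete the block, a 10-trial memory budget ends it
  incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .agents import VirtualSubject
from .fsm import Action, EventPredicate, FSMSpec, StateSpec, TransitionRule
from .protocol import CriterionRule, Protocol, StageSpec, register_builder

__all__ = [
    "JoystickGeometry",
    "CenterOutConfig",
    "LeverTaskConfig",
    "SequenceTaskConfig",
    "BlockRecord",
    "build_center_out_fsm",
    "build_center_out_protocol",
    "build_lever_fsm",
    "update_reward_window",
    "run_sequence_block",
    "draw_next_sequence",
]


@dataclass(frozen=True)
class JoystickGeometry:
    """Inverted-Y slit: a vertical DOWN segment from the equilibrium
    position at the top, and LEFT/RIGHT arms from the junction."""

    down_cm: float = 3.0
    left_cm: float = 6.0
    right_cm: float = 6.0
    init_threshold_cm: float = 2.0

    def __post_init__(self) -> None:
        if min(self.down_cm, self.left_cm, self.right_cm) <= 0:
            raise ValueError("segment lengths must be positive")
        if not (0 < self.init_threshold_cm <= self.down_cm):
            raise ValueError("init threshold must lie on the DOWN segment")


@dataclass(frozen=True)
class CenterOutConfig:
    init_down_cm: float = 2.0
    target_arm_cm: float = 5.0
    timeout_s: float = 7.0
    tone_hz: float = 1000.0
    tone_ms: float = 100.0
    led_center: str = "led-center"
    led_left: str = "led-left"
    led_right: str = "led-right"
    cue_p_left: float = 0.5
    reward_ml: float = 0.04
    geometry: JoystickGeometry = field(default_factory=JoystickGeometry)
    # sub-stage ramps (shaping ladders)
    stage2_down_ramp: tuple = (0.5, 1.0, 1.5, 2.0)
    stage3_lateral_ramp: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)

    def __post_init__(self) -> None:
        if self.target_arm_cm <= 0 or self.timeout_s <= 0:
            raise ValueError("target distance and timeout must be positive")
        if not (0.0 <= self.cue_p_left <= 1.0):
            raise ValueError("cue probability must lie in [0, 1]")


@dataclass(frozen=True)
class LeverTaskConfig:
    target_ipi_ms: float = 700.0
    band_fraction: float = 0.30  # analysis band for 'correct' trials
    lockout_ms: float = 1200.0
    reward_band: tuple = (0.30, 0.40)
    controller_window: int = 50
    shrink: float = 0.95
    expand: float = 1.05
    min_half_width_ms: float = 20.0
    max_half_width_ms: float = 700.0
    initial_half_width_ms: float = 700.0
    second_press_timeout_ms: float = 10_000.0
    tone_hz: float = 1000.0
    tone_ms: float = 100.0
    reward_ml: float = 0.04

    def __post_init__(self) -> None:
        if not (0.0 < self.band_fraction < 1.0):
            raise ValueError("band fraction must be in (0, 1)")
        if self.lockout_ms <= 0:
            raise ValueError("lockout must be positive")
        if self.min_half_width_ms > self.max_half_width_ms:
            raise ValueError("min half-width exceeds max half-width")


@dataclass(frozen=True)
class SequenceTaskConfig:
    sequence_length: int = 2
    alphabet: tuple = ("L", "R")
    guided_consecutive: int = 2  # consecutive correct to enter memory phase
    memory_consecutive: int = 2  # consecutive correct to complete the block
    trial_budget: int = 10  # memory-guided trial budget
    guided_cap: int = 10  # hard cap on guided trials (prevents infinite blocks)
    budget_includes_guided: bool = False
    timeout_s: float = 7.0

    def __post_init__(self) -> None:
        if self.trial_budget < self.memory_consecutive:
            raise ValueError("budget must allow the consecutive-correct requirement")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")


@dataclass
class BlockRecord:
    """One block of the sequence task: a fixed target sequence worked on
    until 2 consecutive correct memory-guided trials or budget exhaustion.

    ``trials`` holds (guided, movements, correct) per trial, movements
    truncated at the first error (an erroneous movement ends the trial).
    ``n_memory_trials`` is the memory trial on which the block completed;
    incomplete blocks are scored at the full budget.
    """

    block_index: int
    target: str
    trials: list = field(default_factory=list)
    completed: bool = False
    n_memory_trials: int = 0

    def to_dict(self) -> dict:
        return {
            "block_index": self.block_index,
            "target": self.target,
            "trials": [
                {"guided": g, "movements": m, "correct": c} for g, m, c in self.trials
            ],
            "completed": self.completed,
            "n_memory_trials": self.n_memory_trials,
        }


# ---------------------------------------------------------------------------
# Lever task
# ---------------------------------------------------------------------------

def build_lever_fsm(
    window: Tuple[float, float],
    config: Optional[LeverTaskConfig] = None,
) -> FSMSpec:
    """Trial machine for the precise lever-pressing task.

    The first press arms the trial; a second press at interval dt is
    rewarded iff ``lo <= dt <= hi`` (closed interval), triggering the
    reward tone and lick-gated dispensing; otherwise a lockout state
    ignores presses for 1.2 s before the error terminal.
    """
    config = config or LeverTaskConfig()
    lo, hi = window
    if not (lo < config.target_ipi_ms < hi):
        raise ValueError("reward window must bracket the target interval")
    tone = Action("speaker", "pulse", {"freq_hz": config.tone_hz, "duration_ms": config.tone_ms})
    valve = Action("valve", "pulse", {"volume_ml": config.reward_ml})
    states = (
        StateSpec("idle"),
        StateSpec("armed", timeout_ms=config.second_press_timeout_ms),
        StateSpec("success-tone", entry_actions=(tone,), timeout_ms=3000.0),
        StateSpec("collected", entry_actions=(valve,)),
        StateSpec("unclaimed"),
        StateSpec("lockout", timeout_ms=config.lockout_ms),
        StateSpec("no-second-press"),
        StateSpec("missed"),
    )
    transitions = (
        TransitionRule("idle", "armed", trigger=EventPredicate("lever")),
        TransitionRule(
            "armed",
            "success-tone",
            trigger=EventPredicate("lever", min_elapsed_ms=lo, max_elapsed_ms=hi),
            priority=0,
        ),
        TransitionRule("armed", "lockout", trigger=EventPredicate("lever"), priority=1),
        TransitionRule("armed", "no-second-press", timeout_ms=config.second_press_timeout_ms, priority=2),
        TransitionRule("success-tone", "collected", trigger=EventPredicate("lick")),
        TransitionRule("success-tone", "unclaimed", timeout_ms=3000.0, priority=1),
        TransitionRule("lockout", "missed", timeout_ms=config.lockout_ms),
    )
    return FSMSpec(
        id=f"lever[{lo:.0f},{hi:.0f}]",
        states=states,
        initial="idle",
        terminals={
            "collected": "rewarded",
            "unclaimed": "rewarded",
            "missed": "error",
            "no-second-press": "timeout",
        },
        transitions=transitions,
    )


def update_reward_window(
    history: Sequence[bool],
    window: Tuple[float, float],
    config: Optional[LeverTaskConfig] = None,
) -> Tuple[float, float]:
    """Adaptive reward contingency for the lever task.

    The window is symmetric about the 700 ms target.  The reward
    fraction over the last ``controller_window`` trials drives a
    multiplicative half-width update: above the band it shrinks, below
    it expands, inside it is left alone; the half-width is clamped to
    ``[min_half_width_ms, max_half_width_ms]``.  With fewer trials than
    the controller window the window is unchanged.
    """
    config = config or LeverTaskConfig()
    lo, hi = window
    target = config.target_ipi_ms
    if abs((target - lo) - (hi - target)) > 1e-9:
        raise ValueError("window must be symmetric about the target interval")
    if len(history) < config.controller_window:
        return window
    recent = history[-config.controller_window:]
    frac = sum(recent) / len(recent)
    half = (hi - lo) / 2.0
    lo_band, hi_band = config.reward_band
    if frac > hi_band:
        half *= config.shrink
    elif frac < lo_band:
        half *= config.expand
    else:
        return window
    half = min(max(half, config.min_half_width_ms), config.max_half_width_ms)
    return (target - half, target + half)


# ---------------------------------------------------------------------------
# Center-out task
# ---------------------------------------------------------------------------

def build_center_out_fsm(params: dict, context: dict) -> FSMSpec:
    """Trial machine for one center-out (sub-)stage.

    ``params['stage']`` selects the shaping variant: ``touch`` (stage 1:
    any joystick contact is rewarded), ``down`` (stage 2: downward
    displacement past ``down_cm``), or ``full`` (stage 3: initiation
    past ``down_cm``, then the cued arm past ``lateral_cm``; wrong-arm
    crossings enter a penalty state lasting ``timeout_s``).
    ``context['cue']`` ('L' or 'R') gives the cued side for stage 3.
    """
    cfg_kwargs = params.get("config", {})
    config = cfg_kwargs if isinstance(cfg_kwargs, CenterOutConfig) else CenterOutConfig(**cfg_kwargs)
    stage = params.get("stage", "full")
    tone = Action("speaker", "pulse", {"freq_hz": config.tone_hz, "duration_ms": config.tone_ms})
    valve = Action("valve", "pulse", {"volume_ml": config.reward_ml})
    timeout_ms = config.timeout_s * 1000.0

    reward_tail_states = (
        StateSpec("success-tone", entry_actions=(tone,), timeout_ms=3000.0),
        StateSpec("collected", entry_actions=(valve,)),
        StateSpec("unclaimed"),
    )
    reward_tail_rules = (
        TransitionRule("success-tone", "collected", trigger=EventPredicate("lick")),
        TransitionRule("success-tone", "unclaimed", timeout_ms=3000.0, priority=1),
    )
    terminals = {"collected": "rewarded", "unclaimed": "rewarded"}

    if stage == "touch":
        states = (
            StateSpec("wait-touch", entry_actions=(Action(config.led_center, "on"),)),
        ) + reward_tail_states
        rules = (
            TransitionRule("wait-touch", "success-tone", trigger=EventPredicate("joystick")),
        ) + reward_tail_rules
        return FSMSpec("center-out/touch", states, "wait-touch", terminals, rules)

    if stage == "down":
        down_cm = float(params.get("down_cm", config.init_down_cm))
        states = (
            StateSpec(
                "wait-down",
                entry_actions=(Action(config.led_center, "on"),),
                timeout_ms=60_000.0,
            ),
            StateSpec("timed-out"),
        ) + reward_tail_states
        rules = (
            TransitionRule(
                "wait-down",
                "success-tone",
                trigger=EventPredicate("joystick", op=">=", value=down_cm, segment="DOWN"),
            ),
            TransitionRule("wait-down", "timed-out", timeout_ms=60_000.0, priority=1),
        ) + reward_tail_rules
        terminals = dict(terminals, **{"timed-out": "timeout"})
        return FSMSpec(f"center-out/down{down_cm:g}", states, "wait-down", terminals, rules)

    # full stage-3 trial: cued left/right movement
    down_cm = float(params.get("down_cm", config.init_down_cm))
    lateral_cm = float(params.get("lateral_cm", config.target_arm_cm))
    cue = context.get("cue", "L")
    cued_seg = "LEFT" if cue == "L" else "RIGHT"
    wrong_seg = "RIGHT" if cue == "L" else "LEFT"
    cue_led = config.led_left if cue == "L" else config.led_right
    states = (
        StateSpec("wait-init", entry_actions=(Action(config.led_center, "on"),), timeout_ms=60_000.0),
        StateSpec("cued", entry_actions=(Action(cue_led, "on"),), timeout_ms=timeout_ms),
        StateSpec("penalty", entry_actions=(Action("house-lights", "off"),), timeout_ms=timeout_ms),
        StateSpec("wrong-arm"),
        StateSpec("timed-out"),
    ) + reward_tail_states
    rules = (
        TransitionRule(
            "wait-init",
            "cued",
            trigger=EventPredicate("joystick", op=">=", value=down_cm, segment="DOWN"),
        ),
        TransitionRule("wait-init", "timed-out", timeout_ms=60_000.0, priority=1),
        TransitionRule(
            "cued",
            "success-tone",
            trigger=EventPredicate("joystick", op=">", value=lateral_cm, segment=cued_seg),
            priority=0,
        ),
        TransitionRule(
            "cued",
            "penalty",
            trigger=EventPredicate("joystick", op=">", value=lateral_cm, segment=wrong_seg),
            priority=1,
        ),
        TransitionRule("cued", "timed-out", timeout_ms=timeout_ms, priority=2),
        TransitionRule("penalty", "wrong-arm", timeout_ms=timeout_ms),
    ) + reward_tail_rules
    terminals = dict(terminals, **{"wrong-arm": "error", "timed-out": "timeout"})
    return FSMSpec(
        f"center-out/full{lateral_cm:g}{cue}", states, "wait-init", terminals, rules
    )


def build_center_out_protocol(config: Optional[CenterOutConfig] = None) -> Protocol:
    """Three-stage shaping ladder for the center-out task.

    Stage 1: touching the joystick for a reward tone and a lick-gated
    reward.  Stage 2 sub-stages ramp the required downward displacement
    up to the initiation threshold.  Stage 3 sub-stages ramp the lateral
    displacement up to the target arm distance, with the full cued trial
    machine.  Sub-stage counts and increments are shipped defaults.
    """
    config = config or CenterOutConfig()
    crit = CriterionRule()
    stages = [StageSpec((1, 1), "center_out", {"stage": "touch"}, crit)]
    for i, d in enumerate(config.stage2_down_ramp, start=1):
        stages.append(StageSpec((2, i), "center_out", {"stage": "down", "down_cm": d}, crit))
    for i, l in enumerate(config.stage3_lateral_ramp, start=1):
        stages.append(
            StageSpec(
                (3, i),
                "center_out",
                {"stage": "full", "down_cm": config.init_down_cm, "lateral_cm": l},
                crit,
            )
        )
    return Protocol(id="center-out", stages=tuple(stages))


def _build_lever_from_params(params: dict, context: dict) -> FSMSpec:
    config = params.get("config")
    if isinstance(config, dict):
        config = LeverTaskConfig(**config)
    config = config or LeverTaskConfig()
    half = context.get("half_width_ms", config.initial_half_width_ms)
    window = (config.target_ipi_ms - half, config.target_ipi_ms + half)
    return build_lever_fsm(window, config)


register_builder("center_out", build_center_out_fsm)
register_builder("lever_press", _build_lever_from_params)


def build_lever_protocol(config: Optional[LeverTaskConfig] = None) -> Protocol:
    """Single-stage lever protocol; the adaptive window does the shaping."""
    return Protocol(
        id="lever-press",
        stages=(
            StageSpec(
                (1, 1),
                "lever_press",
                {"config": config or LeverTaskConfig()},
                CriterionRule(metric="fraction-correct", window=100, threshold=0.7, min_trials=100),
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Memory-guided sequence task
# ---------------------------------------------------------------------------

def draw_next_sequence(
    rng: np.random.Generator,
    config: Optional[SequenceTaskConfig] = None,
) -> str:
    """Draw the next block's target sequence uniformly (LL/LR/RL/RR)."""
    config = config or SequenceTaskConfig()
    idx = rng.integers(0, len(config.alphabet), size=config.sequence_length)
    return "".join(config.alphabet[i] for i in idx)


def _run_one_trial(subject: VirtualSubject, target: str, guided: bool) -> tuple:
    """Score one trial: (guided, recorded movements, correct).

    An erroneous movement ends the trial immediately with a timeout, so
    the recorded movement string is truncated at the first error.
    """
    moves = subject.sequence_movements(list(target), guided)
    recorded = []
    correct = True
    for m, t in zip(moves, target):
        recorded.append(m)
        if m != t:
            correct = False
            break
    return (guided, "".join(recorded), correct and len(recorded) == len(target))


def run_sequence_block(
    target: str,
    subject: VirtualSubject,
    config: Optional[SequenceTaskConfig] = None,
    block_index: int = 0,
) -> BlockRecord:
    """Run one block of the memory-guided sequence task.

    Visually guided trials run until ``guided_consecutive`` correct in a
    row (capped at ``guided_cap``); then cues are removed and
    memory-guided trials run until ``memory_consecutive`` correct in a
    row (``completed``) or the memory-trial budget is exhausted.  With
    ``budget_includes_guided`` the budget counts guided and memory
    trials together, matching the alternative reading of the ten-trial
    rule.
    """
    config = config or SequenceTaskConfig()
    rec = BlockRecord(block_index=block_index, target=target)
    streak = 0
    n_trials = 0

    # guided phase
    while streak < config.guided_consecutive and n_trials < config.guided_cap:
        trial = _run_one_trial(subject, target, guided=True)
        rec.trials.append(trial)
        n_trials += 1
        streak = streak + 1 if trial[2] else 0
    if streak < config.guided_consecutive:
        rec.completed = False
        rec.n_memory_trials = config.trial_budget
        return rec

    # memory phase
    budget = config.trial_budget - (n_trials if config.budget_includes_guided else 0)
    streak = 0
    n_memory = 0
    while n_memory < budget:
        trial = _run_one_trial(subject, target, guided=False)
        rec.trials.append(trial)
        n_memory += 1
        streak = streak + 1 if trial[2] else 0
        if streak >= config.memory_consecutive:
            rec.completed = True
            rec.n_memory_trials = n_memory
            return rec
    rec.completed = False
    rec.n_memory_trials = config.trial_budget
    return rec


def run_lever_series(
    subject: VirtualSubject,
    n_trials: int,
    config: Optional[LeverTaskConfig] = None,
):
    """Drive ``n_trials`` lever trials through the full trial engine with
    the adaptive reward-window controller in the loop.

    Each trial builds the machine for the current window, feeds it the
    agent's presses and lick, scores it, and updates the window from the
    running rewarded-flag history.  Returns ``(ipis_ms, rewarded_flags,
    half_widths_ms)`` as lists of length ``n_trials``.
    """
    from .agents import respond
    from .fsm import run_trial

    config = config or LeverTaskConfig()
    half = config.initial_half_width_ms
    window = (config.target_ipi_ms - half, config.target_ipi_ms + half)
    ipis, flags, halves = [], [], []
    t = 0
    for _ in range(n_trials):
        events = respond(subject, {"task": "lever"}, t_start_us=t)
        spec = build_lever_fsm(window, config)
        trial = run_trial(spec, events, t_start_us=t)
        ipis.append((events[1].t_us - events[0].t_us) / 1000.0)
        flags.append(trial.outcome == "rewarded")
        window = update_reward_window(flags, window, config)
        halves.append((window[1] - window[0]) / 2.0)
        t = trial.t_end + int(config.lockout_ms * 1000) + 1_000_000
    return ipis, flags, halves
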