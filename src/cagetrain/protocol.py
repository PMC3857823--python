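"""Shaping protocols: staged training with criterion-driven advancement.

A protocol is an ordered list of (stage, sub-stage) entries, each pairing
an FSM builder (a named task-library constructor plus parameters) with an
advancement criterion computed over the subject's recent trial outcomes.
The trainer holds each subject's position in the ladder, evaluates the
criterion after every trial, and hands the engine the stage's machine.

Stages only ever advance; there is no demotion.  Subjects that stall are
flagged for reporting (see :meth:`ProtocolState.stalled`), not demoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .fsm import FSMSpec, TrialRecord, validate_fsm

__all__ = [
    "CriterionRule",
    "StageSpec",
    "Protocol",
    "ProtocolState",
    "ConfigurationError",
    "evaluate_criterion",
    "advance",
    "current_fsm",
    "register_builder",
    "get_builder",
]


class ConfigurationError(ValueError):
    """A protocol or builder configuration is malformed."""


METRICS = ("fraction-rewarded", "count-rewarded", "fraction-correct")


@dataclass(frozen=True)
class CriterionRule:
    """Performance criterion over a window of recent trials.

    ``metric`` is one of ``fraction-rewarded`` (outcome == rewarded),
    ``count-rewarded``, or ``fraction-correct`` (the trial's
    ``meta['correct']`` flag, falling back to rewarded).  The rule is
    evaluable only once ``min_trials`` trials of history exist.
    """

    metric: str = "fraction-rewarded"
    window: int = 30
    threshold: float = 0.7
    min_trials: int = 30

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        if self.metric.startswith("fraction") and not (0.0 <= self.threshold <= 1.0):
            raise ConfigurationError("fraction threshold must be in [0, 1]")
        if not (self.window >= self.min_trials >= 1):
            raise ConfigurationError("require window >= min_trials >= 1")


def _is_correct(trial: TrialRecord) -> bool:
    if "correct" in trial.meta:
        return bool(trial.meta["correct"])
    return trial.outcome == "rewarded"


def evaluate_criterion(history: Sequence[TrialRecord], rule: CriterionRule) -> bool:
    """True iff the metric over the last ``window`` trials meets the threshold.

    Always false with fewer than ``min_trials`` trials of history.
    """
    if len(history) < rule.min_trials:
        return False
    recent = history[-rule.window:]
    if rule.metric == "fraction-rewarded":
        value = sum(t.outcome == "rewarded" for t in recent) / len(recent)
    elif rule.metric == "count-rewarded":
        value = float(sum(t.outcome == "rewarded" for t in recent))
    elif rule.metric == "fraction-correct":
        value = sum(_is_correct(t) for t in recent) / len(recent)
    else:  # pragma: no cover - guarded in CriterionRule
        raise ConfigurationError(f"unknown metric {rule.metric!r}")
    return value >= rule.threshold


@dataclass(frozen=True)
class StageSpec:
    """One rung of the ladder: (stage, sub-stage) id, builder, criterion."""

    stage_id: tuple  # (stage, sub_stage)
    builder: str
    params: dict = field(default_factory=dict)
    criterion: CriterionRule = field(default_factory=CriterionRule)


@dataclass(frozen=True)
class Protocol:
    id: str
    stages: tuple

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigurationError("protocol has no stages")
        ids = [s.stage_id for s in self.stages]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ConfigurationError("stage ids must be strictly increasing")

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        stages = []
        for s in d["stages"]:
            crit = s.get("criterion", {})
            stages.append(
                StageSpec(
                    stage_id=tuple(s["stage_id"]),
                    builder=s["builder"],
                    params=dict(s.get("params", {})),
                    criterion=CriterionRule(**crit),
                )
            )
        return cls(id=d["id"], stages=tuple(stages))

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "stages": [
                {
                    "stage_id": list(s.stage_id),
                    "builder": s.builder,
                    "params": dict(s.params),
                    "criterion": {
                        "metric": s.criterion.metric,
                        "window": s.criterion.window,
                        "threshold": s.criterion.threshold,
                        "min_trials": s.criterion.min_trials,
                    },
                }
                for s in self.stages
            ],
        }


@dataclass
class ProtocolState:
    """A subject's position in a protocol, plus promotion bookkeeping."""

    subject_id: str
    stage_index: int = 0
    complete: bool = False
    # history of trials *within the current stage* (cleared on promotion)
    stage_history: list = field(default_factory=list)
    # (stage_index, t_entry_us, t_exit_us or None) per visited stage
    stage_times: list = field(default_factory=list)
    # wall-clock budget (us) without advancement before the subject is
    # flagged as stalled for reporting; None disables the flag
    stall_budget_us: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.stage_times:
            self.stage_times = [[self.stage_index, 0, None]]

    def stalled(self, now_us: int) -> bool:
        if self.stall_budget_us is None or self.complete:
            return False
        entered = self.stage_times[-1][1]
        return now_us - entered > self.stall_budget_us


def advance(state: ProtocolState, new_trial: TrialRecord, protocol: Protocol) -> ProtocolState:
    """Fold one trial into the state; promote when the criterion is met.

    The stage index increments by exactly one per promotion and never
    decrements.  Promotion timestamps are the promoting trial's end
    time.  Meeting the final stage's criterion sets ``complete``.
    Mutates and returns ``state``.
    """
    if state.complete:
        return state
    if not (0 <= state.stage_index < len(protocol.stages)):
        raise ConfigurationError("stage index out of bounds for protocol")
    state.stage_history.append(new_trial)
    stage = protocol.stages[state.stage_index]
    if evaluate_criterion(state.stage_history, stage.criterion):
        t = new_trial.t_end
        state.stage_times[-1][2] = t
        if state.stage_index + 1 < len(protocol.stages):
            state.stage_index += 1
            state.stage_history = []
            state.stage_times.append([state.stage_index, t, None])
        else:
            state.complete = True
    return state


# --- builder registry -------------------------------------------------------

_BUILDERS: dict = {}


def register_builder(name: str, fn: Callable) -> None:
    """Register a named FSM builder ``fn(params, context) -> FSMSpec``."""
    _BUILDERS[name] = fn


def get_builder(name: str) -> Callable:
    try:
        return _BUILDERS[name]
    except KeyError:
        raise ConfigurationError(f"unknown FSM builder {name!r}") from None


def current_fsm(state: ProtocolState, protocol: Protocol, context: Optional[dict] = None) -> FSMSpec:
    """Build the FSM of the subject's current stage.

    ``context`` carries per-trial session/task parameters (e.g. the cued
    side, the current adaptive reward window).  The returned spec is
    guaranteed valid.
    """
    stage = protocol.stages[state.stage_index]
    builder = get_builder(stage.builder)
    spec = builder(dict(stage.params), dict(context or {}))
    problems = validate_fsm(spec)
    if problems:
        raise ConfigurationError(
            f"builder {stage.builder!r} produced an invalid FSM: {problems}"
        )
    return spec
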