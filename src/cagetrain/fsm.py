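"""Finite-state-machine trial control.

A behavioral trial is described declaratively as a small finite state
machine: states carry entry/exit actions (LEDs, tones, valve pulses,
log markers), and transitions are triggered either by input events
(lever presses, licks, joystick threshold crossings) or by a timeout
measured from state entry.  The engine executes one machine — or
several concurrently over a shared event stream — against a virtual
discrete-event clock and returns a fully timestamped :class:`TrialRecord`.

Timestamps are carried in microseconds; the engine's decision
resolution is 1 ms, which is ample for the behavioral constants in the
shipped tasks (100, 700, 1200, 7000 ms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, Sequence

__all__ = [
    "InputEvent",
    "Action",
    "EventPredicate",
    "TransitionRule",
    "StateSpec",
    "FSMSpec",
    "TrialRecord",
    "MonotonicityError",
    "validate_fsm",
    "step",
    "run_trial",
    "run_concurrent",
    "action_volume_ml",
    "VALVE_ML_PER_MS",
]

SCHEMA_VERSION = 1

#: Calibration constant of the virtual solenoid valve: ml dispensed per
#: millisecond of open time.  0.04 ml <=> a 200 ms pulse.
VALVE_ML_PER_MS = 0.0002


class MonotonicityError(ValueError):
    """An event carried a timestamp earlier than the trial clock."""


@dataclass(frozen=True)
class InputEvent:
    """One timestamped input: lever press, lick, joystick sample, marker.

    ``value`` is a scalar for simple channels, or a ``(segment,
    displacement_cm)`` pair on the ``joystick`` channel.
    """

    channel: str
    value: Any
    t_us: int

    def __post_init__(self) -> None:
        if self.t_us < 0:
            raise ValueError(f"negative timestamp: {self.t_us}")

    def to_dict(self) -> dict:
        v = list(self.value) if isinstance(self.value, tuple) else self.value
        return {"t_us": self.t_us, "channel": self.channel, "value": v}

    @classmethod
    def from_dict(cls, d: dict) -> "InputEvent":
        v = d["value"]
        if isinstance(v, list):
            v = tuple(v)
        return cls(channel=d["channel"], value=v, t_us=int(d["t_us"]))


@dataclass(frozen=True)
class Action:
    """An effector command attached to a state or transition.

    ``params`` may carry e.g. ``freq_hz`` and ``duration_ms`` for tones,
    ``open_ms`` or ``volume_ml`` for valve pulses.
    """

    effector: str
    command: str = "pulse"  # on | off | pulse
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("duration_ms", "open_ms", "volume_ml", "freq_hz"):
            v = self.params.get(key)
            if v is not None and v <= 0:
                raise ValueError(f"action param {key} must be > 0, got {v}")

    def to_dict(self) -> dict:
        return {"effector": self.effector, "command": self.command, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Action":
        return cls(d["effector"], d.get("command", "pulse"), dict(d.get("params", {})))


def action_volume_ml(action: Action) -> float:
    """Water-volume equivalent of an action (0 for non-valve effectors)."""
    if action.effector != "valve":
        return 0.0
    if "volume_ml" in action.params:
        return float(action.params["volume_ml"])
    return float(action.params.get("open_ms", 0)) * VALVE_ML_PER_MS


_OPS = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
}


@dataclass(frozen=True)
class EventPredicate:
    """Condition on an input event, optionally gated on time-in-state.

    For the joystick channel the event value is ``(segment,
    displacement_cm)``; ``segment`` selects the arm and the value
    condition applies to the displacement, so threshold crossings are
    decided here rather than by the event source.
    """

    channel: str
    op: Optional[str] = None
    value: Any = None
    segment: Optional[str] = None
    min_elapsed_ms: Optional[float] = None
    max_elapsed_ms: Optional[float] = None

    def matches(self, event: InputEvent, elapsed_in_state_ms: float) -> bool:
        if event.channel != self.channel:
            return False
        if self.min_elapsed_ms is not None and elapsed_in_state_ms < self.min_elapsed_ms:
            return False
        if self.max_elapsed_ms is not None and elapsed_in_state_ms > self.max_elapsed_ms:
            return False
        v = event.value
        if self.segment is not None:
            if not (isinstance(v, tuple) and len(v) == 2):
                return False
            seg, disp = v
            if seg != self.segment:
                return False
            v = disp
        if self.op is not None:
            return _OPS[self.op](v, self.value)
        return True

    def to_dict(self) -> dict:
        d: dict = {"channel": self.channel}
        for k in ("op", "value", "segment", "min_elapsed_ms", "max_elapsed_ms"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EventPredicate":
        return cls(**d)


@dataclass(frozen=True)
class TransitionRule:
    """Edge of the trial machine: event-triggered or timeout-triggered.

    Exactly one of ``trigger`` (an :class:`EventPredicate`) and
    ``timeout_ms`` must be set.  Lower ``priority`` wins when several
    rules from the same source match the same event.
    """

    source: str
    target: str
    trigger: Optional[EventPredicate] = None
    timeout_ms: Optional[float] = None
    priority: int = 0
    actions: tuple = ()  # extra actions emitted on this transition

    def __post_init__(self) -> None:
        if (self.trigger is None) == (self.timeout_ms is None):
            raise ValueError(
                f"rule {self.source}->{self.target}: exactly one of trigger/timeout_ms required"
            )
        if self.timeout_ms is not None and self.timeout_ms < 0:
            raise ValueError("timeout_ms must be >= 0")

    @property
    def is_timeout(self) -> bool:
        return self.timeout_ms is not None

    def to_dict(self) -> dict:
        d: dict = {"source": self.source, "target": self.target, "priority": self.priority}
        if self.trigger is not None:
            d["trigger"] = self.trigger.to_dict()
        if self.timeout_ms is not None:
            d["timeout_ms"] = self.timeout_ms
        if self.actions:
            d["actions"] = [a.to_dict() for a in self.actions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionRule":
        return cls(
            source=d["source"],
            target=d["target"],
            trigger=EventPredicate.from_dict(d["trigger"]) if "trigger" in d else None,
            timeout_ms=d.get("timeout_ms"),
            priority=d.get("priority", 0),
            actions=tuple(Action.from_dict(a) for a in d.get("actions", [])),
        )


@dataclass(frozen=True)
class StateSpec:
    name: str
    entry_actions: tuple = ()
    exit_actions: tuple = ()
    timeout_ms: Optional[float] = None

    def to_dict(self) -> dict:
        d: dict = {"name": self.name}
        if self.entry_actions:
            d["entry_actions"] = [a.to_dict() for a in self.entry_actions]
        if self.exit_actions:
            d["exit_actions"] = [a.to_dict() for a in self.exit_actions]
        if self.timeout_ms is not None:
            d["timeout_ms"] = self.timeout_ms
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpec":
        return cls(
            name=d["name"],
            entry_actions=tuple(Action.from_dict(a) for a in d.get("entry_actions", [])),
            exit_actions=tuple(Action.from_dict(a) for a in d.get("exit_actions", [])),
            timeout_ms=d.get("timeout_ms"),
        )


OUTCOME_LABELS = ("rewarded", "error", "timeout", "aborted", "failure")


@dataclass(frozen=True)
class FSMSpec:
    """Declarative description of one trial machine.

    ``terminals`` maps terminal state names to outcome labels
    (``rewarded | error | timeout | aborted | failure``).
    """

    id: str
    states: tuple
    initial: str
    terminals: dict
    transitions: tuple

    @property
    def state_names(self) -> set:
        return {s.name for s in self.states}

    def state(self, name: str) -> StateSpec:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def rules_from(self, source: str) -> list:
        return sorted(
            (r for r in self.transitions if r.source == source),
            key=lambda r: r.priority,
        )

    # --- serialization (JSON canonical; YAML accepted) ---------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "id": self.id,
            "initial": self.initial,
            "terminals": dict(self.terminals),
            "states": [s.to_dict() for s in self.states],
            "transitions": [t.to_dict() for t in self.transitions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FSMSpec":
        return cls(
            id=d["id"],
            states=tuple(StateSpec.from_dict(s) for s in d["states"]),
            initial=d["initial"],
            terminals=dict(d["terminals"]),
            transitions=tuple(TransitionRule.from_dict(t) for t in d["transitions"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FSMSpec":
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_yaml(cls, text: str) -> "FSMSpec":
        import yaml

        return cls.from_dict(yaml.safe_load(text))


@dataclass
class TrialRecord:
    """Outcome and full trace of one executed trial."""

    fsm_id: str
    outcome: str
    t_start: int
    t_end: int
    state_path: list
    event_trace: list
    actions_emitted: list  # (t_us, Action) pairs
    reward_ml: float = 0.0
    # convenience metadata filled in by task runners
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end < t_start")
        if self.reward_ml < 0:
            raise ValueError("negative reward volume")

    def to_dict(self) -> dict:
        return {
            "fsm_id": self.fsm_id,
            "outcome": self.outcome,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "state_path": list(self.state_path),
            "event_trace": [e.to_dict() for e in self.event_trace],
            "actions_emitted": [[t, a.to_dict()] for t, a in self.actions_emitted],
            "reward_ml": self.reward_ml,
            "meta": dict(self.meta),
        }


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_fsm(spec: FSMSpec) -> list:
    """Return a list of violation descriptions; empty means executable.

    Checks: the initial state is defined, all transition endpoints are
    defined, every terminal is reachable from the initial state,
    rules sharing a source have distinct priorities, and non-terminal
    states are not dead ends (at least one outgoing rule or a timeout).
    """
    violations: list = []
    names = spec.state_names

    seen: set = set()
    for s in spec.states:
        if s.name in seen:
            violations.append(f"duplicate state name: {s.name}")
        seen.add(s.name)

    if spec.initial not in names:
        violations.append(f"initial state undefined: {spec.initial}")
    if not spec.terminals:
        violations.append("no terminal states declared")
    for t, label in spec.terminals.items():
        if t not in names:
            violations.append(f"terminal state undefined: {t}")
        if label not in OUTCOME_LABELS:
            violations.append(f"unknown outcome label {label!r} for terminal {t}")

    for r in spec.transitions:
        if r.source not in names:
            violations.append(f"transition source undefined: {r.source}")
        if r.target not in names:
            violations.append(f"transition target undefined: {r.target}")

    # duplicate priority among rules sharing a source
    by_source: dict = {}
    for r in spec.transitions:
        by_source.setdefault(r.source, []).append(r)
    for src, rules in by_source.items():
        prios = [r.priority for r in rules]
        if len(prios) != len(set(prios)):
            violations.append(f"state {src}: rules with equal priority")

    # reachability of terminals (forward closure from initial)
    if spec.initial in names:
        reach = {spec.initial}
        frontier = [spec.initial]
        while frontier:
            cur = frontier.pop()
            for r in by_source.get(cur, []):
                if r.target in names and r.target not in reach:
                    reach.add(r.target)
                    frontier.append(r.target)
        for t in spec.terminals:
            if t in names and t not in reach:
                violations.append(f"unreachable terminal: {t}")

    # dead ends: non-terminal state with no outgoing rule and no timeout
    for s in spec.states:
        if s.name in spec.terminals:
            continue
        rules = by_source.get(s.name, [])
        has_timeout = s.timeout_ms is not None or any(r.is_timeout for r in rules)
        if not rules and not has_timeout:
            violations.append(f"dead-end state: {s.name}")

    return violations


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def _rule_timeout_us(rule: TransitionRule, state: StateSpec) -> Optional[int]:
    """Effective timeout of a timeout rule in microseconds.

    A timeout rule may state its own delay, or inherit the state's
    ``timeout_ms``.
    """
    if not rule.is_timeout:
        return None
    ms = rule.timeout_ms if rule.timeout_ms else state.timeout_ms
    if ms is None:
        return None
    return int(round(ms * 1000))


def step(
    current_state: str,
    elapsed_in_state_ms: float,
    event: Optional[InputEvent],
    spec: FSMSpec,
):
    """Advance one machine by one event (or clock tick when ``event`` is None).

    Returns ``(next_state, actions)``.  The highest-priority matching
    rule fires; exit actions of the old state, then transition actions,
    then entry actions of the new state are emitted in order.  With no
    matching rule the state is unchanged and no actions are emitted.
    """
    if current_state in spec.terminals:
        raise ValueError(f"cannot step from terminal state {current_state}")
    state = spec.state(current_state)
    fired: Optional[TransitionRule] = None
    for rule in spec.rules_from(current_state):
        if event is None:
            if rule.is_timeout:
                to_us = _rule_timeout_us(rule, state)
                if to_us is not None and elapsed_in_state_ms * 1000 >= to_us:
                    fired = rule
                    break
        else:
            if rule.trigger is not None and rule.trigger.matches(event, elapsed_in_state_ms):
                fired = rule
                break
    if fired is None:
        return current_state, []
    actions = list(state.exit_actions) + list(fired.actions)
    actions += list(spec.state(fired.target).entry_actions)
    return fired.target, actions


class _Machine:
    """Execution state of one FSM instance on the shared clock."""

    def __init__(self, spec: FSMSpec, t_start_us: int):
        self.spec = spec
        self.state = spec.initial
        self.t_entered = t_start_us
        self.t_start = t_start_us
        self.state_path = [spec.initial]
        self.event_trace: list = []
        self.actions: list = []
        self.done = False
        self.outcome: Optional[str] = None
        self.t_end = t_start_us
        for a in spec.state(spec.initial).entry_actions:
            self.actions.append((t_start_us, a))
        self._finish_if_terminal(t_start_us)

    def _finish_if_terminal(self, now_us: int) -> None:
        if self.state in self.spec.terminals:
            self.done = True
            self.outcome = self.spec.terminals[self.state]
            self.t_end = now_us

    def next_deadline_us(self) -> Optional[int]:
        """Earliest time a timeout rule of the current state fires."""
        if self.done:
            return None
        state = self.spec.state(self.state)
        deadlines = []
        for rule in self.spec.rules_from(self.state):
            to_us = _rule_timeout_us(rule, state)
            if to_us is not None:
                deadlines.append(self.t_entered + to_us)
        return min(deadlines) if deadlines else None

    def _fire(self, rule: TransitionRule, now_us: int) -> None:
        state = self.spec.state(self.state)
        for a in state.exit_actions:
            self.actions.append((now_us, a))
        for a in rule.actions:
            self.actions.append((now_us, a))
        self.state = rule.target
        self.t_entered = now_us
        self.state_path.append(rule.target)
        for a in self.spec.state(rule.target).entry_actions:
            self.actions.append((now_us, a))
        self._finish_if_terminal(now_us)

    def offer_event(self, event: InputEvent) -> None:
        if self.done:
            return
        self.event_trace.append(event)
        elapsed_ms = (event.t_us - self.t_entered) / 1000.0
        for rule in self.spec.rules_from(self.state):
            if rule.trigger is not None and rule.trigger.matches(event, elapsed_ms):
                self._fire(rule, event.t_us)
                return

    def fire_timeout(self, now_us: int) -> None:
        if self.done:
            return
        state = self.spec.state(self.state)
        for rule in self.spec.rules_from(self.state):
            to_us = _rule_timeout_us(rule, state)
            if to_us is not None and now_us >= self.t_entered + to_us:
                self._fire(rule, now_us)
                return

    def abort(self, now_us: int) -> None:
        self.done = True
        self.outcome = "aborted"
        self.t_end = now_us

    def record(self) -> TrialRecord:
        reward = sum(action_volume_ml(a) for _, a in self.actions)
        return TrialRecord(
            fsm_id=self.spec.id,
            outcome=self.outcome or "aborted",
            t_start=self.t_start,
            t_end=self.t_end,
            state_path=self.state_path,
            event_trace=self.event_trace,
            actions_emitted=self.actions,
            reward_ml=reward,
        )


def run_concurrent(
    specs: Sequence[FSMSpec],
    events: Iterable[InputEvent],
    t_start_us: int = 0,
    max_transitions: int = 1_000_000,
) -> list:
    """Execute several machines over one shared event stream.

    Every event is offered to all still-running machines in spec order;
    timeout deadlines are honored in global time order (ties broken by
    spec order).  Returns one :class:`TrialRecord` per spec.
    ``max_transitions`` guards against machines whose timeout edges form
    a cycle and would otherwise spin forever once events run out.
    """
    steps = 0
    for spec in specs:
        problems = validate_fsm(spec)
        if problems:
            raise ValueError(f"invalid FSM {spec.id}: {problems}")
    machines = [_Machine(spec, t_start_us) for spec in specs]
    now = t_start_us
    it: Iterator[InputEvent] = iter(events)
    pending: Optional[InputEvent] = next(it, None)

    while any(not m.done for m in machines):
        steps += 1
        if steps > max_transitions:
            raise RuntimeError(
                "transition budget exhausted; the machine likely cycles on timeouts"
            )
        # earliest pending timeout across machines
        deadline = None
        for m in machines:
            d = m.next_deadline_us()
            if d is not None and (deadline is None or d < deadline):
                deadline = d
        if pending is not None and pending.t_us < now:
            raise MonotonicityError(
                f"event at t={pending.t_us}us precedes trial clock t={now}us"
            )
        if deadline is not None and (pending is None or deadline <= pending.t_us):
            now = max(now, deadline)
            for m in machines:
                d = m.next_deadline_us()
                if d is not None and d <= now:
                    m.fire_timeout(now)
        elif pending is not None:
            now = pending.t_us
            for m in machines:
                m.offer_event(pending)
            pending = next(it, None)
        else:
            for m in machines:
                if not m.done:
                    m.abort(now)
    return [m.record() for m in machines]


def run_trial(
    spec: FSMSpec,
    events: Iterable[InputEvent],
    t_start_us: int = 0,
) -> TrialRecord:
    """Execute a single trial machine to a terminal state.

    The machine consumes events until a terminal state is reached; if
    the event source is exhausted with no pending timeout, the outcome
    is ``aborted``.  Deterministic: identical spec and event stream
    yield an identical record.
    """
    return run_concurrent([spec], events, t_start_us)[0]
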