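import numpy as np
import pytest

from cagetrain.fsm import (
    EventPredicate,
    FSMSpec,
    InputEvent,
    StateSpec,
    TransitionRule,
)


@pytest.fixture
def minimal_fsm():
    """Two-state machine: start --(lever press)--> rewarded terminal."""
    return FSMSpec(
        id="minimal",
        states=(StateSpec("start"), StateSpec("done")),
        initial="start",
        terminals={"done": "rewarded"},
        transitions=(TransitionRule("start", "done", trigger=EventPredicate("lever")),),
    )


def make_random_fsm(rng: np.random.Generator, n_states: int = None):
    """Random small machine over event channels 'a'/'b' plus timeouts.

    Predicates are channel-only, so independent interpreters need no
    value semantics; priorities are unique per source by construction.
    """
    n = n_states or int(rng.integers(2, 7))
    names = [f"s{i}" for i in range(n)]
    n_term = int(rng.integers(1, max(2, n // 2 + 1)))
    terminals = {names[-(i + 1)]: "rewarded" for i in range(n_term)}
    transitions = []
    for i, src in enumerate(names):
        if src in terminals:
            continue
        prio = 0
        for ch in ("a", "b"):
            if rng.random() < 0.8:
                transitions.append(
                    TransitionRule(
                        src,
                        names[int(rng.integers(n))],
                        trigger=EventPredicate(ch),
                        priority=prio,
                    )
                )
                prio += 1
        # timeout edges only move forward, so timeout chains always
        # terminate even after the event stream is exhausted
        if (rng.random() < 0.5 or prio == 0) and i + 1 < n:
            transitions.append(
                TransitionRule(
                    src,
                    names[int(rng.integers(i + 1, n))],
                    timeout_ms=float(rng.integers(1, 50) * 100),
                    priority=prio,
                )
            )
    return FSMSpec(
        id="random",
        states=tuple(StateSpec(nm) for nm in names),
        initial=names[0],
        terminals=terminals,
        transitions=tuple(transitions),
    )


def make_event_stream(rng: np.random.Generator, n_events: int = None):
    n = n_events if n_events is not None else int(rng.integers(0, 13))
    t = 0
    events = []
    for _ in range(n):
        t += int(rng.integers(1, 40)) * 100_000  # 0.1-4 s gaps
        events.append(InputEvent(rng.choice(["a", "b"]), 1, t))
    return events


def reference_interpreter(spec: FSMSpec, events):
    """Independent table-driven interpreter used as the execution oracle.

    Works directly off the declarative transition table: at each step the
    earliest timeout deadline competes with the next event; event rules
    match on channel and fire in priority order.  Returns (outcome,
    state_path).
    """
    state = spec.initial
    t_entered = 0
    path = [state]
    idx = 0
    terminals = spec.terminals

    def timeout_deadline(st):
        best = None
        for r in sorted(spec.transitions, key=lambda r: r.priority):
            if r.source == st and r.timeout_ms is not None:
                d = t_entered + int(r.timeout_ms * 1000)
                if best is None or d < best[0]:
                    best = (d, r)
        return best

    while state not in terminals:
        to = timeout_deadline(state)
        ev = events[idx] if idx < len(events) else None
        if to is not None and (ev is None or to[0] <= ev.t_us):
            state = to[1].target
            t_entered = to[0]
            path.append(state)
        elif ev is not None:
            idx += 1
            for r in sorted(spec.transitions, key=lambda r: r.priority):
                if (
                    r.source == state
                    and r.trigger is not None
                    and r.trigger.channel == ev.channel
                ):
                    state = r.target
                    t_entered = ev.t_us
                    path.append(state)
                    break
        else:
            return "aborted", path
    return terminals[state], path
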