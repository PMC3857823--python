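"""Trial-machine engine: validation, dispatch, execution, concurrency."""

import json

import numpy as np
import pytest

from cagetrain.fsm import (
    Action,
    EventPredicate,
    FSMSpec,
    InputEvent,
    MonotonicityError,
    StateSpec,
    TransitionRule,
    action_volume_ml,
    run_concurrent,
    run_trial,
    step,
    validate_fsm,
)

from conftest import make_event_stream, make_random_fsm, reference_interpreter


class TestValidation:
    def test_minimal_machine_is_valid(self, minimal_fsm):
        assert validate_fsm(minimal_fsm) == []

    def test_dangling_target_is_reported(self):
        spec = FSMSpec(
            id="dangling",
            states=(StateSpec("start"), StateSpec("done")),
            initial="start",
            terminals={"done": "rewarded"},
            transitions=(TransitionRule("start", "X", trigger=EventPredicate("lever")),),
        )
        assert any("X" in v for v in validate_fsm(spec))

    def test_equal_priorities_on_shared_source_rejected(self):
        spec = FSMSpec(
            id="dup",
            states=(StateSpec("a"), StateSpec("b")),
            initial="a",
            terminals={"b": "rewarded"},
            transitions=(
                TransitionRule("a", "b", trigger=EventPredicate("x"), priority=1),
                TransitionRule("a", "b", trigger=EventPredicate("y"), priority=1),
            ),
        )
        assert any("equal priority" in v for v in validate_fsm(spec))

    def test_dead_end_state_reported(self):
        spec = FSMSpec(
            id="dead",
            states=(StateSpec("a"), StateSpec("b"), StateSpec("c")),
            initial="a",
            terminals={"c": "rewarded"},
            transitions=(
                TransitionRule("a", "b", trigger=EventPredicate("x")),
                TransitionRule("a", "c", trigger=EventPredicate("y"), priority=1),
            ),
        )
        assert any("dead-end" in v for v in validate_fsm(spec))

    def test_unreachable_terminal_matches_bfs_oracle(self):
        """Over 200 random machines, the 'unreachable terminal' violation
        fires exactly when independent BFS from the initial state fails."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            spec = make_random_fsm(rng)
            # independent BFS over the raw transition table
            adj = {}
            for r in spec.transitions:
                adj.setdefault(r.source, set()).add(r.target)
            seen, frontier = {spec.initial}, [spec.initial]
            while frontier:
                cur = frontier.pop()
                for nxt in adj.get(cur, ()):
                    if nxt not in seen:
                        seen.add(nxt)
                        frontier.append(nxt)
            expected_unreachable = {t for t in spec.terminals if t not in seen}
            flagged = {
                v.split(": ")[1]
                for v in validate_fsm(spec)
                if v.startswith("unreachable terminal")
            }
            assert flagged == expected_unreachable


class TestStep:
    def test_single_rule_dispatch_emits_entry_actions(self):
        led = Action("led-1", "on")
        spec = FSMSpec(
            id="s",
            states=(StateSpec("wait-press"), StateSpec("pressed", entry_actions=(led,))),
            initial="wait-press",
            terminals={"pressed": "rewarded"},
            transitions=(TransitionRule("wait-press", "pressed", trigger=EventPredicate("lever")),),
        )
        nxt, actions = step("wait-press", 0.0, InputEvent("lever", 1, 0), spec)
        assert nxt == "pressed"
        assert led in actions

    def test_priority_tie_break(self):
        spec = FSMSpec(
            id="p",
            states=(StateSpec("a"), StateSpec("b"), StateSpec("c")),
            initial="a",
            terminals={"b": "rewarded", "c": "error"},
            transitions=(
                TransitionRule("a", "c", trigger=EventPredicate("x"), priority=2),
                TransitionRule("a", "b", trigger=EventPredicate("x"), priority=1),
            ),
        )
        nxt, _ = step("a", 0.0, InputEvent("x", 1, 0), spec)
        assert nxt == "b"

    def test_no_match_leaves_state_unchanged(self, minimal_fsm):
        nxt, actions = step("start", 0.0, InputEvent("lick", 1, 0), minimal_fsm)
        assert nxt == "start" and actions == []

    def test_timeout_fires_after_seven_seconds(self):
        """A 7 s timeout state transitions on the clock tick at 7000 ms."""
        spec = FSMSpec(
            id="t",
            states=(StateSpec("penalty", timeout_ms=7000.0), StateSpec("out")),
            initial="penalty",
            terminals={"out": "timeout"},
            transitions=(TransitionRule("penalty", "out", timeout_ms=7000.0),),
        )
        assert step("penalty", 6999.0, None, spec)[0] == "penalty"
        assert step("penalty", 7000.0, None, spec)[0] == "out"


def _lever_like_spec():
    from cagetrain.tasks import build_lever_fsm

    return build_lever_fsm((600.0, 800.0))


class TestRunTrial:
    def test_two_presses_700ms_apart_rewarded(self):
        events = [
            InputEvent("lever", 1, 0),
            InputEvent("lever", 1, 700_000),
            InputEvent("lick", 1, 800_000),
        ]
        rec = run_trial(_lever_like_spec(), events)
        assert rec.outcome == "rewarded"
        assert rec.reward_ml > 0

    def test_empty_stream_without_timeout_aborts(self, minimal_fsm):
        rec = run_trial(minimal_fsm, [])
        assert rec.outcome == "aborted"

    def test_replay_reproduces_identical_record(self):
        events = [
            InputEvent("lever", 1, 0),
            InputEvent("lever", 1, 300_000),
        ]
        spec = _lever_like_spec()
        first = run_trial(spec, events)
        replay = run_trial(spec, list(first.event_trace))
        assert replay.to_dict() == first.to_dict()

    def test_event_before_clock_raises(self, minimal_fsm):
        with pytest.raises(MonotonicityError):
            run_trial(minimal_fsm, [InputEvent("lever", 1, 0)], t_start_us=10)

    def test_record_invariants_on_random_machines(self):
        """state_path follows declared rules; traces are time-ordered."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(300):
            spec = make_random_fsm(rng)
            if validate_fsm(spec):
                continue
            rec = run_trial(spec, make_event_stream(rng))
            checked += 1
            assert rec.t_end >= rec.t_start
            assert rec.state_path[0] == spec.initial
            edges = {(r.source, r.target) for r in spec.transitions}
            for a, b in zip(rec.state_path, rec.state_path[1:]):
                assert (a, b) in edges
            times_e = [e.t_us for e in rec.event_trace]
            assert times_e == sorted(times_e)
            times_a = [t for t, _ in rec.actions_emitted]
            assert times_a == sorted(times_a)
            if rec.outcome != "aborted":
                assert spec.terminals[rec.state_path[-1]] == rec.outcome
        assert checked > 100

    def test_matches_independent_interpreter(self):
        """Engine == table-driven reference interpreter on small machines
        (<= 6 states) and short streams (<= 12 events)."""
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(500):
            spec = make_random_fsm(rng)
            if validate_fsm(spec):
                continue
            events = make_event_stream(rng)
            rec = run_trial(spec, events)
            outcome, path = reference_interpreter(spec, events)
            checked += 1
            assert rec.outcome == outcome
            assert rec.state_path == path
        assert checked > 150


class TestConcurrent:
    def test_non_interference_with_cue_machine(self, minimal_fsm):
        cue = FSMSpec(
            id="cue",
            states=(StateSpec("on", timeout_ms=10_000.0), StateSpec("off")),
            initial="on",
            terminals={"off": "timeout"},
            transitions=(TransitionRule("on", "off", timeout_ms=10_000.0),),
        )
        events = [InputEvent("lever", 1, 500_000)]
        alone = run_trial(minimal_fsm, events)
        both = run_concurrent([minimal_fsm, cue], events)
        assert both[0].to_dict() == alone.to_dict()
        assert both[1].outcome == "timeout"

    def test_two_copies_yield_identical_records(self, minimal_fsm):
        events = [InputEvent("lever", 1, 100_000)]
        a, b = run_concurrent([minimal_fsm, minimal_fsm], events)
        assert a.to_dict() == b.to_dict()

    def test_watchdog_machine_flags_heartbeat_gap(self, minimal_fsm):
        """A heartbeat-timeout machine beside a trial machine reaches its
        failure terminal when heartbeats stop for longer than its window."""
        watchdog = FSMSpec(
            id="watchdog",
            states=(StateSpec("alive", timeout_ms=2000.0), StateSpec("dead")),
            initial="alive",
            terminals={"dead": "failure"},
            transitions=(
                TransitionRule("alive", "alive", trigger=EventPredicate("heartbeat")),
                TransitionRule("alive", "dead", timeout_ms=2000.0, priority=1),
            ),
        )
        events = [
            InputEvent("heartbeat", 1, 1_000_000),
            InputEvent("heartbeat", 1, 2_000_000),
            # gap > 2 s: watchdog should trip at t = 4 s
            InputEvent("lever", 1, 6_000_000),
        ]
        trial, dog = run_concurrent([minimal_fsm, watchdog], events)
        assert dog.outcome == "failure"
        assert dog.t_end == 4_000_000
        assert trial.outcome == "rewarded"


class TestSerialization:
    def test_json_round_trip_is_lossless(self):
        spec = _lever_like_spec()
        again = FSMSpec.from_json(spec.to_json())
        assert again == spec
        assert json.loads(again.to_json()) == json.loads(spec.to_json())

    def test_yaml_accepted(self):
        import yaml

        spec = _lever_like_spec()
        text = yaml.safe_dump(spec.to_dict())
        assert FSMSpec.from_yaml(text) == spec

    def test_event_jsonl_round_trip(self):
        ev = InputEvent("joystick", ("LEFT", 5.1), 123)
        assert InputEvent.from_dict(json.loads(json.dumps(ev.to_dict()))) == ev


def test_valve_volume_from_open_duration():
    a = Action("valve", "pulse", {"open_ms": 200})
    assert action_volume_ml(a) == pytest.approx(0.04)
    assert action_volume_ml(Action("led-1", "on")) == 0.0
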