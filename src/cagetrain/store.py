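"""Append-only event persistence and the colony experiment runner.

Events, trials and blocks are persisted to a single-file embedded
SQLite store (a desk-scale stand-in for a central database); the store
is append-only — records are never updated or deleted.
:func:`run_experiment` wires the whole stack together: the scheduler
opens nightly sessions, the trainer supplies each subject's current
trial machine, virtual subjects supply events, the engine produces
trial records, and water ledgers are settled at end of night.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analytics, schedule as sched, tasks
from .agents import AgentPolicy, VirtualSubject, respond
from .fsm import InputEvent, run_trial
from .protocol import ConfigurationError, Protocol, ProtocolState, advance, current_fsm

__all__ = [
    "EventRecord",
    "EventStore",
    "ExperimentConfig",
    "run_experiment",
]


@dataclass(frozen=True)
class EventRecord:
    run_id: str
    box_id: str
    subject_id: str
    t_us: int
    channel: str
    value: str
    fsm_id: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        if self.t_us < 0:
            raise ValueError("negative timestamp")


class EventStore:
    """Single-file append-only event log with a small query API."""

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS events (
        run_id TEXT NOT NULL,
        box_id TEXT NOT NULL,
        subject_id TEXT NOT NULL,
        t_us INTEGER NOT NULL,
        channel TEXT NOT NULL,
        value TEXT NOT NULL,
        fsm_id TEXT NOT NULL,
        state TEXT NOT NULL
    );
    CREATE INDEX IF NOT EXISTS idx_events_run_t ON events (run_id, t_us);
    """

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(self._SCHEMA)

    def close(self) -> None:
        self._conn.close()

    def append(self, records) -> int:
        """Durably append a batch; a single invalid record rejects the
        whole batch and writes nothing."""
        rows = []
        for r in records:
            if not isinstance(r, EventRecord):
                raise TypeError(f"expected EventRecord, got {type(r).__name__}")
            rows.append(
                (r.run_id, r.box_id, r.subject_id, r.t_us, r.channel, r.value, r.fsm_id, r.state)
            )
        with self._conn:
            self._conn.executemany(
                "INSERT INTO events VALUES (?, ?, ?, ?, ?, ?, ?, ?)", rows
            )
        return len(rows)

    def query(
        self,
        t_min: Optional[int] = None,
        t_max: Optional[int] = None,
        subject_id: Optional[str] = None,
        channel: Optional[str] = None,
        run_id: Optional[str] = None,
    ) -> list:
        """Records matching all given filter clauses, in timestamp order."""
        if t_min is not None and t_max is not None and t_min > t_max:
            raise ValueError("malformed time range: t_min > t_max")
        clauses, params = [], []
        for col, val in (
            ("t_us >= ?", t_min),
            ("t_us <= ?", t_max),
            ("subject_id = ?", subject_id),
            ("channel = ?", channel),
            ("run_id = ?", run_id),
        ):
            if val is not None:
                clauses.append(col)
                params.append(val)
        sql = "SELECT run_id, box_id, subject_id, t_us, channel, value, fsm_id, state FROM events"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY t_us, channel"
        return [EventRecord(*row) for row in self._conn.execute(sql, params)]

    def count(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM events").fetchone()[0]


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

_TASKS = ("lever_press", "sequence_task", "center_out")
_AGENTS = ("chance", "bernoulli", "learning", "timing", "scripted", "perfect", "never")


@dataclass
class ExperimentConfig:
    """Declarative colony simulation: subjects, task, schedule, horizon."""

    run_id: str
    task: str
    subjects: list  # dicts: id, body_weight_g, agent {variant, params}
    horizon_nights: int = 3
    seed: int = 0
    schedule: dict = field(default_factory=dict)
    task_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        problems = cls.validate_dict(d)
        if problems:
            raise ConfigurationError("; ".join(problems))
        return cls(
            run_id=d["run_id"],
            task=d["task"],
            subjects=list(d["subjects"]),
            horizon_nights=int(d.get("horizon_nights", 3)),
            seed=int(d.get("seed", 0)),
            schedule=dict(d.get("schedule", {})),
            task_params=dict(d.get("task_params", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @staticmethod
    def validate_dict(d: dict) -> list:
        """Schema check with actionable field-level messages."""
        problems = []
        for key in ("run_id", "task", "subjects"):
            if key not in d:
                problems.append(f"missing required field {key!r}")
        if d.get("task") not in _TASKS:
            problems.append(f"task: expected one of {_TASKS}, got {d.get('task')!r}")
        for i, s in enumerate(d.get("subjects", []) or []):
            where = f"subjects[{i}]"
            if "id" not in s:
                problems.append(f"{where}.id missing")
            if s.get("body_weight_g", 0) <= 0:
                problems.append(f"{where}.body_weight_g must be positive")
            agent = s.get("agent", {})
            if agent.get("variant") not in _AGENTS:
                problems.append(
                    f"{where}.agent.variant: expected one of {_AGENTS}, got {agent.get('variant')!r}"
                )
        if d.get("horizon_nights", 1) < 1:
            problems.append("horizon_nights must be >= 1")
        return problems


# ---------------------------------------------------------------------------
# Colony simulation
# ---------------------------------------------------------------------------

_US_PER_MIN = 60_000_000


def _night_start_us(night: int) -> int:
    return night * 24 * 60 * _US_PER_MIN


class _SubjectRuntime:
    def __init__(self, spec: dict, cfg: ExperimentConfig, seed_seq: np.random.SeedSequence):
        self.id = spec["id"]
        self.ledger = sched.WaterLedger(self.id, spec["body_weight_g"])
        agent = spec.get("agent", {"variant": "perfect"})
        rng = np.random.default_rng(seed_seq)
        self.subject = VirtualSubject(
            AgentPolicy(agent["variant"], dict(agent.get("params", {}))), rng
        )
        self.rng = np.random.default_rng(seed_seq.spawn(1)[0])
        self.trials: list = []
        self.blocks: list = []
        self.reward_flags: list = []
        if cfg.task == "lever_press":
            self.lever_cfg = tasks.LeverTaskConfig(**cfg.task_params.get("lever_press", {}))
            hw = self.lever_cfg.initial_half_width_ms
            self.window = (
                self.lever_cfg.target_ipi_ms - hw,
                self.lever_cfg.target_ipi_ms + hw,
            )
        elif cfg.task == "sequence_task":
            self.seq_cfg = tasks.SequenceTaskConfig(**cfg.task_params.get("sequence_task", {}))
        elif cfg.task == "center_out":
            co_params = cfg.task_params.get("center_out", {})
            self.co_cfg = tasks.CenterOutConfig(**co_params)
            self.protocol = tasks.build_center_out_protocol(self.co_cfg)
            self.pstate = ProtocolState(subject_id=self.id)


def _offset_events(events, offset_us: int):
    return [InputEvent(e.channel, e.value, e.t_us + offset_us) for e in events]


def _store_trial(store, cfg, subj, trial, night):
    recs = [
        EventRecord(
            cfg.run_id, f"box-{subj.id}", subj.id, e.t_us, e.channel,
            json.dumps(e.to_dict()["value"]), trial.fsm_id, "",
        )
        for e in trial.event_trace
    ]
    store.append(recs)


def _run_lever_session(cfg, subj, store, t0_us, minutes, night):
    end_us = t0_us + int(minutes * _US_PER_MIN)
    t = t0_us
    while t < end_us:
        events = respond(subj.subject, {"task": "lever"}, t_start_us=t)
        spec = tasks.build_lever_fsm(subj.window, subj.lever_cfg)
        trial = run_trial(spec, events, t_start_us=t)
        ipi_ms = (events[1].t_us - events[0].t_us) / 1000.0
        trial.meta["ipi_ms"] = ipi_ms
        trial.meta["night"] = night
        rewarded = trial.outcome == "rewarded"
        subj.reward_flags.append(rewarded)
        subj.window = tasks.update_reward_window(subj.reward_flags, subj.window, subj.lever_cfg)
        subj.ledger.credit_earned(trial.reward_ml)
        subj.trials.append(trial)
        _store_trial(store, cfg, subj, trial, night)
        t = max(trial.t_end, t + 1) + 2 * 1_000_000  # 2 s inter-trial interval
    return


def _run_sequence_session(cfg, subj, store, t0_us, minutes, night):
    end_us = t0_us + int(minutes * _US_PER_MIN)
    t = t0_us
    # ~5 s per trial of virtual session time
    while t < end_us:
        target = tasks.draw_next_sequence(subj.rng, subj.seq_cfg)
        block = tasks.run_sequence_block(target, subj.subject, subj.seq_cfg, len(subj.blocks))
        block_trials = len(block.trials)
        n_correct = sum(c for _, _, c in block.trials)
        subj.ledger.credit_earned(n_correct * 0.04)
        subj.blocks.append((night, block))
        t += block_trials * 5_000_000


def _run_center_out_session(cfg, subj, store, t0_us, minutes, night):
    end_us = t0_us + int(minutes * _US_PER_MIN)
    t = t0_us
    while t < end_us and not subj.pstate.complete:
        cue = "L" if subj.rng.random() < subj.co_cfg.cue_p_left else "R"
        stage = subj.protocol.stages[subj.pstate.stage_index]
        context = {
            "cue": cue,
            "task": "center_out",
            "down_cm": stage.params.get("down_cm", subj.co_cfg.init_down_cm),
            "lateral_cm": stage.params.get("lateral_cm", subj.co_cfg.target_arm_cm),
        }
        spec = current_fsm(subj.pstate, subj.protocol, context)
        events = respond(subj.subject, context, t_start_us=t)
        trial = run_trial(spec, events, t_start_us=t)
        trial.meta["night"] = night
        trial.meta["stage"] = list(stage.stage_id)
        subj.ledger.credit_earned(trial.reward_ml)
        subj.trials.append(trial)
        advance(subj.pstate, trial, subj.protocol)
        _store_trial(store, cfg, subj, trial, night)
        t = max(trial.t_end, t + 1) + 2_000_000


_SESSION_RUNNERS = {
    "lever_press": _run_lever_session,
    "sequence_task": _run_sequence_session,
    "center_out": _run_center_out_session,
}


def run_experiment(config: ExperimentConfig, out_dir, store_path=None) -> dict:
    """Simulate the colony for the configured horizon and write summaries.

    Returns a dict of output paths.  Fully reproducible: identical
    (config, seed) yield byte-identical summary files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store = EventStore(store_path or out / "events.sqlite")
    nights = sched.build_schedule(n_nights=config.horizon_nights, **config.schedule)
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(len(config.subjects))
    subjects = [
        _SubjectRuntime(s, config, ss) for s, ss in zip(config.subjects, subj_seeds)
    ]
    runner = _SESSION_RUNNERS[config.task]
    cue = sched.default_cue_sequence()

    ledger_rows = []
    for night_sched in nights:
        night = night_sched.night_index
        base_us = _night_start_us(night)
        if night_sched.is_rest:
            for subj in subjects:
                # ad libitum water, modeled as lick-gated aliquots up to need
                subj.ledger.free_ml += subj.ledger.daily_minimum_ml
                ledger_rows.append(_ledger_row(subj, night, rest=True))
                subj.ledger.next_day()
            continue
        for window in night_sched.windows:
            t0 = base_us + int(window.start_min * _US_PER_MIN)
            if window.kind == "training":
                for subj in subjects:
                    subj.ledger.credit_earned(cue.priming_ml)
                    runner(config, subj, store, t0, window.duration_min, night)
            elif window.kind == "free_water":
                for subj in subjects:
                    sched.free_water_topup(subj.ledger)
        for subj in subjects:
            ledger_rows.append(_ledger_row(subj, night, rest=False))
            subj.ledger.next_day()

    paths = _write_outputs(out, config, subjects, ledger_rows)
    store.close()
    return paths


def _ledger_row(subj, night, rest):
    led = subj.ledger
    return {
        "subject_id": led.subject_id,
        "night": night,
        "rest": rest,
        "body_weight_g": led.body_weight_g,
        "earned_ml": led.earned_ml,
        "free_ml": led.free_ml,
        "total_ml": led.total_ml,
        "minimum_ml": led.daily_minimum_ml,
        "floor_met": led.total_ml >= led.daily_minimum_ml - 1e-9,
    }


def _write_outputs(out: Path, config: ExperimentConfig, subjects, ledger_rows) -> dict:
    ledger_path = out / "ledger.csv"
    pd.DataFrame(ledger_rows).to_csv(ledger_path, index=False)

    trial_rows = []
    for subj in subjects:
        for i, t in enumerate(subj.trials):
            trial_rows.append(
                {
                    "subject_id": subj.id,
                    "trial": i,
                    "night": t.meta.get("night"),
                    "fsm_id": t.fsm_id,
                    "outcome": t.outcome,
                    "t_start_us": t.t_start,
                    "t_end_us": t.t_end,
                    "reward_ml": t.reward_ml,
                    "ipi_ms": t.meta.get("ipi_ms"),
                }
            )
    trials_path = out / "trials.csv"
    pd.DataFrame(trial_rows).to_csv(trials_path, index=False)

    summary: dict = {"run_id": config.run_id, "task": config.task, "seed": config.seed, "subjects": {}}
    for subj in subjects:
        s: dict = {"n_trials": len(subj.trials)}
        nights_seen = {r["night"] for r in ledger_rows if r["subject_id"] == subj.id}
        if subj.trials:
            s["n_rewarded"] = sum(t.outcome == "rewarded" for t in subj.trials)
            s["trials_per_night"] = round(len(subj.trials) / max(len(nights_seen), 1), 3)
        if config.task == "lever_press" and subj.trials:
            ipis = [t.meta["ipi_ms"] for t in subj.trials if "ipi_ms" in t.meta]
            s["fraction_correct"] = round(analytics.correct_fraction(ipis), 4)
            s["final_half_width_ms"] = round((subj.window[1] - subj.window[0]) / 2.0, 3)
        if config.task == "sequence_task" and subj.blocks:
            blocks = [b for _, b in subj.blocks]
            s["n_blocks"] = len(blocks)
            s["fraction_completed_blocks"] = round(
                sum(b.completed for b in blocks) / len(blocks), 4
            )
            done = [b.n_memory_trials for b in blocks if b.completed]
            if done:
                s["mean_memory_trials_completed"] = round(sum(done) / len(done), 4)
        if config.task == "center_out":
            s["stage_index"] = subj.pstate.stage_index
            s["protocol_complete"] = subj.pstate.complete
        s["floor_met_all_nights"] = all(
            r["floor_met"] for r in ledger_rows if r["subject_id"] == subj.id
        )
        summary["subjects"][subj.id] = s
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"ledger": ledger_path, "trials": trials_path, "summary": summary_path}
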