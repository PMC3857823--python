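"""Session scheduling, water accounting, and safety supervision.

Training happens in short sessions spread through the animal's
subjective night (modeled as a 12 h window).  Each session opens with a
salient cue sequence — blinking house lights, a 10 s 1 kHz tone, and a
few priming drops of water.  Water is earned in-session, dispensed only
upon licking the reward spout, and each subject is topped up to the
daily minimum of 5 ml per 100 g body weight at end of night.  A
watchdog monitors component heartbeats and projected water intake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .fsm import Action, InputEvent

__all__ = [
    "SessionWindow",
    "NightSchedule",
    "WaterLedger",
    "CueSequence",
    "ScheduleConfigError",
    "DAILY_MIN_ML_PER_G",
    "NIGHT_MINUTES",
    "build_schedule",
    "free_water_topup",
    "dispense_on_lick",
    "watchdog_check",
    "default_cue_sequence",
]


class ScheduleConfigError(ValueError):
    pass


#: Daily water minimum: 5 ml per 100 g body weight.
DAILY_MIN_ML_PER_G = 0.05

#: Subjective night length in minutes (12 h dark phase of the light cycle).
NIGHT_MINUTES = 12 * 60


@dataclass(frozen=True)
class SessionWindow:
    kind: str  # training | free_water | rest
    start_min: float  # minutes from subjective-night onset
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ScheduleConfigError("window duration must be > 0")
        if self.kind not in ("training", "free_water", "rest"):
            raise ScheduleConfigError(f"unknown window kind {self.kind!r}")

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


def default_cue_sequence(
    n_drops: int = 3, drop_ml: float = 0.01, blink_count: int = 10
) -> "CueSequence":
    """The session-start cue: blinking house lights, a continuous 10 s
    1 kHz tone, and a few drops of priming water (3 x 0.01 ml by default)."""
    return CueSequence(
        actions=(
            Action("house-lights", "pulse", {"duration_ms": 500.0, "count": blink_count}),
            Action("speaker", "pulse", {"freq_hz": 1000.0, "duration_ms": 10_000.0}),
            Action("valve", "pulse", {"volume_ml": n_drops * drop_ml}),
        )
    )


@dataclass(frozen=True)
class CueSequence:
    actions: tuple

    def __post_init__(self) -> None:
        for a in self.actions:
            if a.effector == "speaker":
                if a.params.get("freq_hz", 1) <= 0 or a.params.get("duration_ms", 1) <= 0:
                    raise ScheduleConfigError("tone frequency/duration must be positive")

    @property
    def priming_ml(self) -> float:
        from .fsm import action_volume_ml

        return sum(action_volume_ml(a) for a in self.actions)


@dataclass(frozen=True)
class NightSchedule:
    night_index: int
    windows: tuple
    cue: CueSequence = field(default_factory=default_cue_sequence)

    def __post_init__(self) -> None:
        starts = [w.start_min for w in self.windows]
        if starts != sorted(starts):
            raise ScheduleConfigError("windows must be sorted by start time")
        if self.is_rest and len(self.windows) != 1:
            raise ScheduleConfigError("rest night must contain only the rest window")

    @property
    def is_rest(self) -> bool:
        return any(w.kind == "rest" for w in self.windows)

    def training_windows(self) -> list:
        return [w for w in self.windows if w.kind == "training"]


def build_schedule(
    sessions_per_night: int = 6,
    session_minutes: float = 30.0,
    spacing_hours: float = 2.0,
    rest_day_period: int = 7,
    n_nights: int = 7,
    free_water_minutes: float = 30.0,
) -> list:
    """Build the nightly schedule sequence.

    Non-rest nights carry ``sessions_per_night`` training windows at the
    stated spacing, followed by one free-water settlement window; every
    ``rest_day_period``-th night is a rest night with ad libitum water.
    All windows must fit inside the 12 h subjective night.
    """
    if sessions_per_night < 0:
        raise ScheduleConfigError("sessions_per_night must be >= 0")
    spacing_min = spacing_hours * 60.0
    if sessions_per_night > 1 and spacing_min < session_minutes:
        raise ScheduleConfigError("session spacing shorter than session duration")
    nights = []
    for night in range(n_nights):
        if rest_day_period and (night + 1) % rest_day_period == 0:
            windows = (SessionWindow("rest", 0.0, NIGHT_MINUTES),)
        else:
            ws = [
                SessionWindow("training", i * spacing_min, session_minutes)
                for i in range(sessions_per_night)
            ]
            fw_start = ws[-1].end_min if ws else 0.0
            ws.append(SessionWindow("free_water", fw_start, free_water_minutes))
            windows = tuple(ws)
        last_end = max(w.end_min for w in windows)
        if last_end > NIGHT_MINUTES:
            raise ScheduleConfigError(
                f"night {night}: windows extend to {last_end:.0f} min, beyond the "
                f"{NIGHT_MINUTES} min subjective night"
            )
        nights.append(NightSchedule(night_index=night, windows=windows))
    return nights


@dataclass
class WaterLedger:
    """Per-subject daily water accounting."""

    subject_id: str
    body_weight_g: float
    earned_ml: float = 0.0
    free_ml: float = 0.0
    day_index: int = 0

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")
        if self.earned_ml < 0 or self.free_ml < 0:
            raise ValueError("negative ledger volume")

    @property
    def daily_minimum_ml(self) -> float:
        return DAILY_MIN_ML_PER_G * self.body_weight_g

    @property
    def total_ml(self) -> float:
        return self.earned_ml + self.free_ml

    def credit_earned(self, ml: float) -> None:
        if ml < 0:
            raise ValueError("negative earned volume")
        self.earned_ml += ml

    def next_day(self) -> None:
        self.day_index += 1
        self.earned_ml = 0.0
        self.free_ml = 0.0


def free_water_topup(ledger: WaterLedger) -> float:
    """End-of-night settlement: top the subject up to the daily minimum.

    Returns the dispensed volume ``max(0, 0.05 ml/g x weight - earned)``
    and credits it to the ledger's free-water column.
    """
    if ledger.earned_ml < 0:
        raise ValueError("negative earned volume")
    topup = max(0.0, ledger.daily_minimum_ml - ledger.earned_ml)
    ledger.free_ml += topup
    return topup


def dispense_on_lick(pending_reward_ml: float, lick_event: Optional[InputEvent]) -> float:
    """Lick-gated dispensing: water flows only when the spout is licked.

    Returns the dispensed volume — the full armed reward if a lick event
    is present, otherwise 0 (the reward expires at trial end).
    """
    if pending_reward_ml < 0:
        raise ValueError("pending reward must be >= 0")
    if lick_event is not None and lick_event.channel == "lick":
        return pending_reward_ml
    return 0.0


def watchdog_check(
    heartbeats: dict,
    ledger: WaterLedger,
    now_us: int,
    heartbeat_timeout_us: dict | int = 120_000_000,
    night_elapsed_fraction: Optional[float] = None,
) -> list:
    """Run the supervisory checks; returns a list of alert strings.

    One alert per component whose heartbeat is older than its timeout
    (default 2 min).  If ``night_elapsed_fraction`` is given, intake so
    far is linearly projected to end of night and an alert is raised
    when the projection falls below the daily minimum (the settlement
    top-up will still enforce the floor; the alert is early warning).
    """
    alerts = []
    for component, last_seen in heartbeats.items():
        timeout = (
            heartbeat_timeout_us.get(component, 120_000_000)
            if isinstance(heartbeat_timeout_us, dict)
            else heartbeat_timeout_us
        )
        if now_us - last_seen > timeout:
            silent_s = (now_us - last_seen) / 1e6
            alerts.append(f"component {component} silent for {silent_s:.0f}s")
    if night_elapsed_fraction is not None and night_elapsed_fraction > 0:
        projected = ledger.earned_ml / night_elapsed_fraction
        if projected < ledger.daily_minimum_ml:
            alerts.append(
                f"subject {ledger.subject_id}: projected intake "
                f"{projected:.2f} ml below minimum {ledger.daily_minimum_ml:.2f} ml"
            )
    return alerts
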