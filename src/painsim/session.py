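"""Three-day game session: clock, day goals, unmanageable-pain events,
help-line consult, star scoring, and inner-monologue feedback.

A session is three simulated 24-hour days (09:00 to 09:00), each with its
own goal. Day 1 asks the player to take as little medication as possible;
days 2 and 3 ask them to keep pain strictly under an NRS threshold (3,
then 5). Each day ends with a 1-3 star rating for goal achievement.

Once per day, with configured probability, an unmanageable-pain episode
may trigger at a random minute: pain is floored at 8 and stops responding
to medication until the player calls the help line, after which pain
drops to 5 (never raised if already lower).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Protocol

import numpy as np

from .errors import ConfigurationError, ContractViolation, ScriptingError
from .simulation_core import MINUTES_PER_DAY, Engine, PainModelParams
from .telemetry import TelemetryLog
from .world import Activity, TaskList, perform_activity, tasklist_for_day

GOAL_KINDS = frozenset({"minimize_doses", "pain_under_threshold"})


@dataclass(frozen=True)
class DayGoal:
    day_index: int
    kind: str
    description: str
    threshold: Optional[int] = None  # NRS, pain_under_threshold only

    def __post_init__(self) -> None:
        if self.kind not in GOAL_KINDS:
            raise ConfigurationError(f"unknown goal kind {self.kind!r}")
        if self.kind == "pain_under_threshold" and self.threshold is None:
            raise ConfigurationError("pain_under_threshold goal needs a threshold")


@dataclass(frozen=True)
class StarRating:
    day_index: int
    stars: int
    achieved_fraction: float

    def __post_init__(self) -> None:
        if self.stars not in (1, 2, 3):
            raise ContractViolation("stars must be in {1, 2, 3}")


@dataclass(frozen=True)
class UnmanageableEventConfig:
    probability: float = 0.3
    pain_floor: float = 8.0
    post_consult_pain: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ConfigurationError("event probability must be in [0, 1]")


@dataclass(frozen=True)
class MonologueConfig:
    flavor_rate: float = 0.02  # per decision point
    pain_thresholds: tuple[float, ...] = (3.0, 5.0, 8.0)
    flavor_messages: tuple[str, ...] = ("...",)
    medication_working: str = "I can feel the medication working..."
    pain_rising: str = "My pain is getting worse."
    pain_easing: str = "The pain is easing off."


@dataclass
class GameConfig:
    """Everything a session needs, bundled."""

    medications: dict[str, Any]
    params: PainModelParams
    activities: dict[str, Activity]
    tasks_by_day: dict[int, list[str]]
    goals: dict[int, DayGoal]
    event: UnmanageableEventConfig = field(default_factory=UnmanageableEventConfig)
    monologue: MonologueConfig = field(default_factory=MonologueConfig)
    star_threshold_three: float = 0.95
    star_threshold_two: float = 0.6
    dose_ceiling: int = 8  # tablets at which the day-1 fraction reaches 0


class Policy(Protocol):
    """A scripted player: maps (engine state, task list) to an action.

    Actions are plain dicts:
      {"type": "idle"}
      {"type": "dose", "med_id": str, "tablets": int}
      {"type": "activity", "id": str}
      {"type": "consult"}
    """

    id: str

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]: ...


# ---------------------------------------------------------------------
# events and consult
# ---------------------------------------------------------------------


def trigger_unmanageable(engine: Engine, cfg: UnmanageableEventConfig) -> None:
    s = engine.state
    s.unmanageable_active = True
    s.pain = max(s.pain, cfg.pain_floor)
    engine.log.add(s.clock, "event_trigger", event="unmanageable_pain")


def maybe_trigger_unmanageable(
    engine: Engine, cfg: UnmanageableEventConfig, rng: np.random.Generator
) -> bool:
    """One Bernoulli draw; on success the episode starts immediately."""
    if engine.state.unmanageable_active:
        raise ContractViolation("unmanageable episode already active")
    if rng.random() < cfg.probability:
        trigger_unmanageable(engine, cfg)
        return True
    return False


def schedule_unmanageable(
    cfg: UnmanageableEventConfig, rng: np.random.Generator, dt: int
) -> Optional[int]:
    """The once-per-day draw: a uniformly random trigger minute, or None.

    Both draws are always consumed so that the per-day random stream does
    not depend on the outcome.
    """
    u = rng.random()
    minute = int(rng.integers(0, MINUTES_PER_DAY // dt)) * dt
    return minute if u < cfg.probability else None


def consult_help(engine: Engine, cfg: UnmanageableEventConfig) -> None:
    """Help-line consult: clears the episode; pain drops to the
    post-consult level if above it, and is never raised. Idempotent."""
    s = engine.state
    s.unmanageable_active = False
    s.pain = min(s.pain, cfg.post_consult_pain)
    engine.log.add(s.clock, "consult", pain_after=s.pain)


# ---------------------------------------------------------------------
# monologue
# ---------------------------------------------------------------------


def monologue(
    engine: Engine,
    prev_pain: float,
    prev_relief: float,
    rng: np.random.Generator,
    cfg: MonologueConfig,
) -> Optional[str]:
    """Inner-monologue bubble for the current decision point, if any.

    Status messages are deterministic: medication-working when applied
    relief is rising, a pain message when pain crossed a configured
    threshold since the previous check. Otherwise a random flavor message
    at ``flavor_rate``. The flavor draw is consumed every call so the
    random stream is state-independent.
    """
    flavor_u = rng.random()
    flavor_i = int(rng.integers(0, max(1, len(cfg.flavor_messages))))
    s = engine.state
    relief = engine.applied_relief()
    if relief > prev_relief + 1e-9:
        return cfg.medication_working
    for thr in cfg.pain_thresholds:
        if prev_pain < thr <= s.pain:
            return cfg.pain_rising
        if s.pain < thr <= prev_pain:
            return cfg.pain_easing
    if cfg.flavor_messages and flavor_u < cfg.flavor_rate:
        return cfg.flavor_messages[flavor_i]
    return None


# ---------------------------------------------------------------------
# day and session drivers
# ---------------------------------------------------------------------


def run_day(
    engine: Engine,
    goal: DayGoal,
    policy: Policy,
    cfg: GameConfig,
    event_rng: np.random.Generator,
    monologue_rng: np.random.Generator,
    tasklist: Optional[TaskList] = None,
) -> tuple[TaskList, TelemetryLog]:
    """Simulate exactly 1440 in-game minutes driven by ``policy``.

    The engine's log is replaced with a fresh one for the day; it is
    returned together with the day's task list. The clock must sit at
    09:00 of the goal's day on entry.
    """
    s = engine.state
    day_start = (goal.day_index - 1) * MINUTES_PER_DAY
    if s.clock != day_start:
        raise ContractViolation(
            f"run_day expects clock at {day_start}, found {s.clock}"
        )
    s.day_index = goal.day_index
    s.tablets_today = {}
    if tasklist is None:
        tasklist = tasklist_for_day(goal.day_index, cfg.tasks_by_day)

    day_log = TelemetryLog()
    engine.log = day_log
    day_end = day_start + MINUTES_PER_DAY
    event_minute = schedule_unmanageable(cfg.event, event_rng, engine.params.dt)
    event_fired = False

    while s.clock < day_end:
        if (
            event_minute is not None
            and not event_fired
            and s.clock - day_start >= event_minute
            and not s.unmanageable_active
        ):
            trigger_unmanageable(engine, cfg.event)
            event_fired = True

        prev_pain, prev_relief = s.pain, engine.applied_relief()
        action = policy.decide(engine, tasklist)
        advanced = _dispatch(engine, action, tasklist, cfg, day_end)
        if not advanced:
            engine.step()

        msg = monologue(engine, prev_pain, prev_relief, monologue_rng, cfg.monologue)
        if msg is not None:
            day_log.add(s.clock, "monologue", text=msg)

    return tasklist, day_log


def _dispatch(
    engine: Engine,
    action: dict[str, Any],
    tasklist: TaskList,
    cfg: GameConfig,
    day_end: int,
) -> bool:
    """Apply one policy action; returns True when it advanced the clock."""
    if not isinstance(action, dict) or "type" not in action:
        raise ScriptingError(f"malformed action at clock {engine.state.clock}: {action!r}")
    kind = action["type"]
    if kind == "idle":
        return False
    if kind == "dose":
        try:
            engine.take_dose(action["med_id"], int(action["tablets"]))
        except KeyError as exc:
            raise ScriptingError(
                f"dose action missing field {exc} at clock {engine.state.clock}"
            ) from None
        return False
    if kind == "consult":
        consult_help(engine, cfg.event)
        return False
    if kind == "activity":
        act_id = action.get("id")
        if act_id not in cfg.activities:
            raise ScriptingError(
                f"unknown activity {act_id!r} at clock {engine.state.clock}"
            )
        return perform_activity(
            engine, cfg.activities[act_id], tasklist, stop_clock=day_end
        )
    raise ScriptingError(f"unknown action type {kind!r} at clock {engine.state.clock}")


# ---------------------------------------------------------------------
# goal evaluation
# ---------------------------------------------------------------------


def evaluate_goal(
    day_log: TelemetryLog, goal: DayGoal, cfg: GameConfig
) -> StarRating:
    """Score one complete day log against its goal.

    pain_under_threshold: achieved fraction = share of pain samples
    strictly under the threshold. minimize_doses: fraction falls linearly
    from 1 at zero tablets to 0 at the configured ceiling. Stars: 3 at
    fraction >= 0.95, 2 at >= 0.6, else 1 (thresholds configurable).
    """
    samples = day_log.of_kind("pain_sample")
    expected = cfg.params.steps_per_day
    if len(samples) < expected:
        raise ContractViolation(
            f"incomplete day log: {len(samples)} pain samples, expected {expected}"
        )
    if goal.kind == "pain_under_threshold":
        under = sum(1 for e in samples if e.payload["pain"] < goal.threshold)
        fraction = under / len(samples)
    else:  # minimize_doses
        tablets = sum(e.payload["tablets"] for e in day_log.of_kind("dose"))
        fraction = max(0.0, 1.0 - tablets / cfg.dose_ceiling)
    if fraction >= cfg.star_threshold_three:
        stars = 3
    elif fraction >= cfg.star_threshold_two:
        stars = 2
    else:
        stars = 1
    return StarRating(
        day_index=goal.day_index, stars=stars, achieved_fraction=fraction
    )


# ---------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------


@dataclass
class SessionResult:
    day_logs: list[TelemetryLog]
    ratings: list[StarRating]
    tasklists: list[TaskList]
    final_state: Any

    def summary(self) -> dict[str, Any]:
        return {
            "days": len(self.day_logs),
            "stars": [r.stars for r in self.ratings],
            "achieved_fractions": [
                round(r.achieved_fraction, 6) for r in self.ratings
            ],
            "tasks_completed": [
                sorted(t.completed) for t in self.tasklists
            ],
            "tablets_per_day": [
                sum(e.payload["tablets"] for e in log.of_kind("dose"))
                for log in self.day_logs
            ],
        }


def session_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """(event, monologue, policy) generators, independently derived."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]


def run_session(
    cfg: GameConfig,
    policy_factory: Callable[[np.random.Generator], Policy],
    seed: int,
    days: Optional[int] = None,
) -> SessionResult:
    """Run one full game session (all configured days, default 3)."""
    event_rng, mono_rng, policy_rng = session_rngs(seed)
    policy = policy_factory(policy_rng)
    engine = Engine(
        cfg.medications, cfg.params, pain_floor=cfg.event.pain_floor
    )
    day_indices = sorted(cfg.goals)
    if days is not None:
        day_indices = day_indices[:days]
    logs, ratings, tasklists = [], [], []
    for day in day_indices:
        goal = cfg.goals[day]
        tasklist, day_log = run_day(engine, goal, policy, cfg, event_rng, mono_rng)
        logs.append(day_log)
        tasklists.append(tasklist)
        ratings.append(evaluate_goal(day_log, goal, cfg))
    return SessionResult(
        day_logs=logs, ratings=ratings, tasklists=tasklists,
        final_state=engine.state,
    )


# ---------------------------------------------------------------------
# scripted replay
# ---------------------------------------------------------------------


class ScriptedPolicy:
    """Replays a fixed list of (clock_minute, action) pairs; idles between."""

    id = "scripted"

    def __init__(self, actions: list[tuple[int, dict[str, Any]]]):
        self._actions = sorted(actions, key=lambda x: x[0])
        self._i = 0

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        if self._i < len(self._actions) and self._actions[self._i][0] <= engine.state.clock:
            action = self._actions[self._i][1]
            self._i += 1
            return action
        return {"type": "idle"}


def script_from_log(day_log: TelemetryLog) -> ScriptedPolicy:
    """Rebuild the day's action script (including refused attempts) from
    its telemetry, so the day can be replayed through the simulator."""
    actions: list[tuple[int, dict[str, Any]]] = []
    for e in day_log:
        if e.kind == "dose":
            actions.append(
                (e.time, {"type": "dose", "med_id": e.payload["med_id"],
                          "tablets": e.payload["tablets"]})
            )
        elif e.kind == "activity":
            actions.append((e.time, {"type": "activity", "id": e.payload["id"]}))
        elif e.kind == "consult":
            actions.append((e.time, {"type": "consult"}))
        elif e.kind == "refusal":
            p = e.payload
            if p.get("action") == "dose":
                actions.append(
                    (e.time, {"type": "dose", "med_id": p["med_id"],
                              "tablets": p["tablets"]})
                )
            elif p.get("action") == "activity":
                actions.append((e.time, {"type": "activity", "id": p["id"]}))
    return ScriptedPolicy(actions)
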