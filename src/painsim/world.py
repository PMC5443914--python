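"""Activity catalog and daily task list.

Activities are the household chores, self-care, rest, and distraction
actions a player schedules. Performing one advances the in-game clock
(movement-requiring activities take longer at high pain) and applies its
signed pain effect through the same relaxation dynamics as medication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .simulation_core import MINUTES_PER_DAY, Engine

ACTIVITY_KINDS = frozenset({"chore", "selfcare", "rest", "distraction"})


@dataclass(frozen=True)
class Activity:
    id: str
    kind: str
    duration: int  # nominal in-game minutes
    pain_effect: float  # negative = relieving, positive = impairing
    requires_movement: bool
    counts_toward_tasks: bool

    def __post_init__(self) -> None:
        if self.kind not in ACTIVITY_KINDS:
            raise ConfigurationError(f"{self.id}: unknown activity kind {self.kind!r}")
        if self.duration <= 0:
            raise ConfigurationError(f"{self.id}: duration must be positive")


@dataclass
class TaskList:
    """Required activities for one day and which have been done."""

    day_index: int
    required: list[str]
    completed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.completed <= set(self.required):
            raise ConfigurationError("completed tasks not a subset of required")


def remaining_tasks(tasklist: TaskList) -> list[str]:
    """Required minus completed, preserving the required order."""
    return [t for t in tasklist.required if t not in tasklist.completed]


def classify_effect(pain_effect: float) -> str:
    if pain_effect < 0:
        return "relieving"
    if pain_effect > 0:
        return "impairing"
    return "neutral"


def perform_activity(
    engine: Engine,
    activity: Activity,
    tasklist: TaskList | None = None,
    stop_clock: int | None = None,
) -> bool:
    """Perform ``activity`` now; returns False when it was refused.

    Movement-requiring activities are blocked at or above the immobility
    threshold (refusal logged) and otherwise take duration/mobility
    minutes, rounded up to whole simulation steps. The activity's pain
    effect is active as a target offset for exactly that long. The clock
    never advances past ``stop_clock`` (the end of the current day).
    """
    s, p = engine.state, engine.params
    if activity.requires_movement and s.pain >= p.immobility_threshold:
        engine.log.add(
            s.clock, "refusal",
            action="activity", id=activity.id, reason="immobile",
        )
        return False

    actual = activity.duration
    if activity.requires_movement:
        actual = activity.duration / s.mobility
    nsteps = max(1, math.ceil(actual / p.dt))
    if stop_clock is not None:
        nsteps = min(nsteps, (stop_clock - s.clock) // p.dt)
        if nsteps <= 0:
            return False

    engine.log.add(
        s.clock, "activity",
        id=activity.id,
        activity_kind=activity.kind,
        pain_effect=activity.pain_effect,
        duration_actual=nsteps * p.dt,
        classification=classify_effect(activity.pain_effect),
    )
    if activity.pain_effect != 0.0:
        engine.add_activity_effect(activity.pain_effect, s.clock + nsteps * p.dt)
    for _ in range(nsteps):
        engine.step()
    if (
        activity.counts_toward_tasks
        and tasklist is not None
        and activity.id in tasklist.required
    ):
        tasklist.completed.add(activity.id)
    return True


def tasklist_for_day(day_index: int, tasks_by_day: dict[int, list[str]]) -> TaskList:
    return TaskList(day_index=day_index, required=list(tasks_by_day.get(day_index, [])))
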