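"""Fixture generation: scripted player policies and synthetic respondents.

The built-in policies operationalize the pain-management strategies the
game contrasts: taking nothing, waiting for severe pain (PRN), dosing on
a regular schedule, and relying on rest/distraction. A seeded random
policy exists for fuzzing. Synthetic questionnaire respondents use the
simplest controllable models: item-independent Bernoulli correctness for
the knowledge test (with an additive probability uplift pre to post) and
a truncated, discretized Gaussian for Likert-type items. These are test
fixtures, not claims about real respondents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Optional

import numpy as np

from .instruments import InstrumentSpec, ResponseSheet
from .session import GameConfig, Policy
from .simulation_core import Engine
from .world import TaskList, remaining_tasks

# ---------------------------------------------------------------------
# player policies
# ---------------------------------------------------------------------

#: dosing order used by the medicating policies: (med_id, tablets)
_DOSE_PRIORITY = (
    ("paracetamol", 2),
    ("ibuprofen", 1),
    ("paracetamol_codeine", 2),
    ("tramadol", 2),
)

_REST_CYCLE = ("rest_sofa", "watch_tv", "lie_bed", "use_computer")


def _consult_if_needed(engine: Engine) -> Optional[dict[str, Any]]:
    if engine.state.unmanageable_active:
        return {"type": "consult"}
    return None


def _next_task(engine: Engine, tasklist: TaskList, cfg: GameConfig) -> Optional[dict[str, Any]]:
    for act_id in remaining_tasks(tasklist):
        act = cfg.activities[act_id]
        if act.requires_movement and engine.state.pain >= cfg.params.immobility_threshold:
            continue
        return {"type": "activity", "id": act_id}
    return None


class _CyclingRest:
    """Shared helper: cycle through rest/distraction activities."""

    def __init__(self, cfg: GameConfig):
        self._cycle = [a for a in _REST_CYCLE if a in cfg.activities] or list(cfg.activities)
        self._i = 0

    def next_action(self) -> dict[str, Any]:
        act = self._cycle[self._i % len(self._cycle)]
        self._i += 1
        return {"type": "activity", "id": act}


class NoMedPolicy:
    """Never doses; does the day's tasks, then rests and distracts."""

    id = "no_med"

    def __init__(self, cfg: GameConfig):
        self._cfg = cfg
        self._rest = _CyclingRest(cfg)

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        return (
            _consult_if_needed(engine)
            or _next_task(engine, tasklist, self._cfg)
            or self._rest.next_action()
        )


class PrnWaitForSeverePolicy:
    """Doses only once pain reaches the severe threshold (default 7)."""

    id = "prn_wait_for_severe"

    def __init__(self, cfg: GameConfig, threshold: float = 7.0):
        self._cfg = cfg
        self.threshold = threshold
        self._rest = _CyclingRest(cfg)

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        consult = _consult_if_needed(engine)
        if consult:
            return consult
        if engine.state.pain >= self.threshold:
            for med_id, tablets in _DOSE_PRIORITY:
                if med_id in engine.medications and engine.can_take(med_id, tablets):
                    return {"type": "dose", "med_id": med_id, "tablets": tablets}
        return _next_task(engine, tasklist, self._cfg) or self._rest.next_action()


class ScheduledDosingPolicy:
    """Doses each medication on a regular clock, within all limits."""

    id = "scheduled_dosing"

    def __init__(self, cfg: GameConfig):
        self._cfg = cfg
        self._rest = _CyclingRest(cfg)

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        consult = _consult_if_needed(engine)
        if consult:
            return consult
        for med_id, tablets in _DOSE_PRIORITY:
            if med_id in engine.medications and engine.can_take(med_id, tablets):
                return {"type": "dose", "med_id": med_id, "tablets": tablets}
        return _next_task(engine, tasklist, self._cfg) or self._rest.next_action()


class RestAndDistractPolicy:
    """No medication focus: tasks first thing, then continuous rest and
    distraction; calls for help when pain is unmanageable."""

    id = "rest_and_distract"

    def __init__(self, cfg: GameConfig):
        self._cfg = cfg
        self._rest = _CyclingRest(cfg)

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        return (
            _consult_if_needed(engine)
            or _next_task(engine, tasklist, self._cfg)
            or self._rest.next_action()
        )


class RandomPolicy:
    """Seeded fuzzing policy emitting uniformly random well-formed actions."""

    id = "random"

    def __init__(self, cfg: GameConfig, rng: np.random.Generator):
        self._cfg = cfg
        self._rng = rng
        self._act_ids = sorted(cfg.activities)
        self._med_ids = sorted(cfg.medications)

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        r = self._rng
        kind = r.choice(("idle", "dose", "activity", "consult"), p=(0.35, 0.2, 0.4, 0.05))
        if kind == "dose":
            med_id = self._med_ids[int(r.integers(0, len(self._med_ids)))]
            max_tabs = self._cfg.medications[med_id].max_tablets_per_dose
            return {
                "type": "dose",
                "med_id": med_id,
                "tablets": int(r.integers(1, max_tabs + 1)),
            }
        if kind == "activity":
            return {"type": "activity", "id": self._act_ids[int(r.integers(0, len(self._act_ids)))]}
        return {"type": str(kind)}


class ReliefMaintainerPolicy:
    """Keeps medication relief topped up: doses ahead of wear-off whenever
    the forecast relief over the next hour dips below a target, and rests
    in bed otherwise. Used to script fully-achieved pain-threshold days."""

    id = "relief_maintainer"

    def __init__(self, cfg: GameConfig, target_relief: float = 4.0, rest_id: str = "lie_bed"):
        self._cfg = cfg
        self.target_relief = target_relief
        self._rest_id = rest_id

    def decide(self, engine: Engine, tasklist: TaskList) -> dict[str, Any]:
        from .simulation_core import dose_relief

        s = engine.state
        if s.unmanageable_active:
            return {"type": "consult"}
        horizon = s.clock + 60
        forecast = sum(
            dose_relief(d, engine.medications[d.med_id], horizon)
            for d in s.active_doses
            if d.time_taken <= horizon
        )
        if forecast < self.target_relief:
            for med_id, tablets in _DOSE_PRIORITY:
                if med_id in engine.medications and engine.can_take(med_id, tablets):
                    return {"type": "dose", "med_id": med_id, "tablets": tablets}
        if self._rest_id in self._cfg.activities:
            return {"type": "activity", "id": self._rest_id}
        return {"type": "idle"}


def builtin_policies(cfg: GameConfig) -> dict[str, Callable[[np.random.Generator], Policy]]:
    """Factories for the built-in policies, keyed by id. Each factory
    takes the session's policy RNG (only ``random`` consumes it)."""
    return {
        "no_med": lambda rng: NoMedPolicy(cfg),
        "prn_wait_for_severe": lambda rng: PrnWaitForSeverePolicy(cfg),
        "scheduled_dosing": lambda rng: ScheduledDosingPolicy(cfg),
        "rest_and_distract": lambda rng: RestAndDistractPolicy(cfg),
        "random": lambda rng: RandomPolicy(cfg, rng),
    }


# ---------------------------------------------------------------------
# synthetic questionnaire respondents
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class RespondentModel:
    """Item-independent response model for pre/post knowledge sheets.

    ``p_correct`` is the per-item probability of answering correctly at
    pre; ``uplift`` is added on the probability scale (clipped to [0, 1])
    at post. Incorrect answers pick uniformly among the wrong options,
    "do not know" included.
    """

    n: int
    p_correct: float = 0.54
    uplift: float = 0.0
    likert_mean: float = 3.5
    likert_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_correct <= 1.0):
            raise ValueError("p_correct must be in [0, 1]")
        if self.n < 1:
            raise ValueError("need at least one respondent")


def _knowledge_sheet(
    spec: InstrumentSpec,
    respondent: str,
    timepoint: str,
    p: float,
    rng: np.random.Generator,
) -> ResponseSheet:
    answers = {}
    for item in spec.items:
        if rng.random() < p:
            answers[item.id] = item.correct
        else:
            wrong = [o for o in range(1, (spec.n_options or 6) + 1) if o != item.correct]
            answers[item.id] = int(rng.choice(wrong))
    return ResponseSheet(
        respondent=respondent, instrument=spec.name, answers=answers, timepoint=timepoint
    )


def generate_respondents(
    model: RespondentModel, spec: InstrumentSpec
) -> tuple[list[ResponseSheet], list[ResponseSheet]]:
    """Seeded pre/post knowledge sheets for ``model.n`` respondents."""
    rng = np.random.default_rng(model.seed)
    p_post = float(np.clip(model.p_correct + model.uplift, 0.0, 1.0))
    pre, post = [], []
    for i in range(model.n):
        rid = f"r{i + 1:03d}"
        pre.append(_knowledge_sheet(spec, rid, "pre", model.p_correct, rng))
        post.append(_knowledge_sheet(spec, rid, "post", p_post, rng))
    return pre, post


def generate_likert_sheets(
    spec: InstrumentSpec,
    n: int,
    mean: float,
    sd: float,
    seed: int,
    timepoint: Optional[str] = None,
) -> list[ResponseSheet]:
    """Truncated, discretized Gaussian responses on the instrument scale."""
    rng = np.random.default_rng(seed)
    sheets = []
    for i in range(n):
        draws = rng.normal(mean, sd, size=len(spec.items))
        vals = np.clip(np.rint(draws), spec.scale_min, spec.scale_max).astype(int)
        answers = {item.id: int(v) for item, v in zip(spec.items, vals)}
        sheets.append(
            ResponseSheet(
                respondent=f"r{i + 1:03d}",
                instrument=spec.name,
                answers=answers,
                timepoint=timepoint,
            )
        )
    return sheets
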