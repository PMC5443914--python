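"""Discrete-time dynamics of pain, analgesia, side effects, and mobility.

The avatar's pain is a 0-10 numeric-rating-scale (NRS) value that relaxes
toward a moving target:

    target = clamp(baseline(t) - min(relief_cap, sum of dose relief)
                               + sum of active activity effects, 0, 10)

Each dose contributes a triangular relief curve: zero before ``onset``,
linear rise to ``tablets * peak_relief`` at ``time_to_peak``, linear decay
back to zero at ``effect_duration``. During an unmanageable-pain episode
medication relief is ignored and pain is floored at the episode floor
until a help consult clears it.

All quantities are in in-game minutes; the clock counts minutes since
09:00 of day 1, so day ``d`` spans ``[(d-1)*1440, d*1440)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, ContractViolation
from .telemetry import TelemetryLog

MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------

SIDE_EFFECT_IDS = frozenset(
    {"nausea", "drowsiness", "constipation", "stomach_irritation"}
)

#: metrics a side-effect trigger may threshold on, evaluated at dose time
#: (the just-taken dose included):
#:   active_tablets  -- tablets of this medication not yet worn off
#:   daily_tablets   -- cumulative tablets of this medication today
TRIGGER_METRICS = frozenset({"active_tablets", "daily_tablets"})


@dataclass(frozen=True)
class SideEffectRule:
    effect_id: str
    metric: str
    threshold: int
    duration: int  # minutes the effect stays active

    def __post_init__(self) -> None:
        if self.effect_id not in SIDE_EFFECT_IDS:
            raise ConfigurationError(f"unknown side effect {self.effect_id!r}")
        if self.metric not in TRIGGER_METRICS:
            raise ConfigurationError(f"unknown trigger metric {self.metric!r}")
        if self.threshold < 1:
            raise ConfigurationError("side-effect threshold must be >= 1")
        if self.duration <= 0:
            raise ConfigurationError("side-effect duration must be positive")


@dataclass(frozen=True)
class MedicationSpec:
    """A named analgesic with dose limits and onset/peak/wash-out kinetics."""

    id: str
    tablet_strength: str
    max_tablets_per_dose: int
    max_tablets_per_day: int
    min_dose_interval: int
    onset: int
    time_to_peak: int
    effect_duration: int
    peak_relief: float  # NRS points per tablet
    side_effect_rules: tuple[SideEffectRule, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "max_tablets_per_dose",
            "max_tablets_per_day",
            "min_dose_interval",
            "onset",
            "time_to_peak",
            "effect_duration",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ConfigurationError(f"{self.id}: {name} must be a positive integer")
        if not (self.onset < self.time_to_peak < self.effect_duration):
            raise ConfigurationError(
                f"{self.id}: need onset < time_to_peak < effect_duration"
            )
        if not (0 < self.peak_relief <= 10):
            raise ConfigurationError(f"{self.id}: peak_relief must be in (0, 10]")


@dataclass(frozen=True)
class DoseEvent:
    med_id: str
    tablets: int
    time_taken: int

    def __post_init__(self) -> None:
        if self.tablets < 1:
            raise ContractViolation("tablets must be >= 1")


@dataclass(frozen=True)
class ActivityEffect:
    """Transient pain offset contributed by an in-progress activity."""

    magnitude: float  # signed NRS points; negative = relieving
    expiry: int  # clock minute at which the offset vanishes


@dataclass(frozen=True)
class PainModelParams:
    """Parametrization of the pain dynamics (config-borne, not a claim)."""

    baseline_curve: dict[int, list[tuple[float, float]]]  # day -> (hour, NRS) anchors
    relief_cap: float = 8.0
    relaxation_rate: float = 0.02  # per minute
    dt: int = 5
    min_mobility: float = 0.2
    immobility_threshold: float = 9.0

    def __post_init__(self) -> None:
        if not (0 < self.relief_cap <= 10):
            raise ConfigurationError("relief_cap must be in (0, 10]")
        if self.relaxation_rate <= 0:
            raise ConfigurationError("relaxation_rate must be positive")
        if self.dt <= 0 or MINUTES_PER_DAY % self.dt != 0:
            raise ConfigurationError("dt must divide 1440")
        if not (0 < self.min_mobility <= 1):
            raise ConfigurationError("min_mobility must be in (0, 1]")
        for day, anchors in self.baseline_curve.items():
            if not anchors:
                raise ConfigurationError(f"day {day}: empty baseline anchors")
            hours = [h for h, _ in anchors]
            if hours != sorted(hours):
                raise ConfigurationError(f"day {day}: baseline anchors unordered")
            for _, v in anchors:
                if not (0 <= v <= 10):
                    raise ConfigurationError(f"day {day}: baseline outside [0, 10]")

    @property
    def steps_per_day(self) -> int:
        return MINUTES_PER_DAY // self.dt


@dataclass
class SimState:
    """The avatar's instantaneous state."""

    clock: int = 0
    day_index: int = 1
    pain: float = 0.0
    baseline_pain: float = 0.0
    mobility: float = 1.0
    unmanageable_active: bool = False
    active_doses: list[DoseEvent] = field(default_factory=list)
    active_side_effects: dict[str, int] = field(default_factory=dict)  # id -> expiry
    activity_effects: list[ActivityEffect] = field(default_factory=list)
    tablets_today: dict[str, int] = field(default_factory=dict)
    last_dose_time: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------
# pure functions
# ---------------------------------------------------------------------


def mobility_factor(pain: float, min_mobility: float = 0.2) -> float:
    """Map pain to a movement-speed factor: 1 at pain 0, linearly down to
    ``min_mobility`` at pain 10. Non-increasing in pain."""
    if not (0 <= pain <= 10):
        raise ContractViolation(f"pain {pain} outside [0, 10]")
    return 1.0 - (1.0 - min_mobility) * pain / 10.0


def dose_relief(dose: DoseEvent, spec: MedicationSpec, t: int | float) -> float:
    """Relief (NRS points) contributed by one dose at clock time ``t``.

    Zero before onset, linear rise to the tablet-scaled peak, linear decay
    to zero at effect_duration; continuous in ``t``.
    """
    if t < dose.time_taken:
        raise ContractViolation("relief queried before the dose was taken")
    elapsed = t - dose.time_taken
    peak = dose.tablets * spec.peak_relief
    if elapsed < spec.onset:
        return 0.0
    if elapsed < spec.time_to_peak:
        return peak * (elapsed - spec.onset) / (spec.time_to_peak - spec.onset)
    if elapsed < spec.effect_duration:
        return peak * (
            1.0
            - (elapsed - spec.time_to_peak)
            / (spec.effect_duration - spec.time_to_peak)
        )
    return 0.0


def baseline_pain(params: PainModelParams, clock: int) -> float:
    """Piecewise-linear baseline at ``clock``; days beyond the last
    configured one reuse the last day's anchors."""
    day = clock // MINUTES_PER_DAY + 1
    if day not in params.baseline_curve:
        day = max(params.baseline_curve)
    anchors = params.baseline_curve[day]
    hour = (clock % MINUTES_PER_DAY) / 60.0
    hours = [h for h, _ in anchors]
    values = [v for _, v in anchors]
    return float(np.interp(hour, hours, values))


# ---------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------


class Engine:
    """Owns one avatar's state, the medication table, and the current log.

    The engine is fully deterministic: all randomness (event scheduling,
    monologue) lives in the session layer, so two engines fed the same
    action sequence produce bit-identical trajectories.
    """

    def __init__(
        self,
        medications: dict[str, MedicationSpec],
        params: PainModelParams,
        log: Optional[TelemetryLog] = None,
        pain_floor: float = 8.0,
    ):
        self.medications = medications
        self.params = params
        self.log = log if log is not None else TelemetryLog()
        self.pain_floor = pain_floor
        self.state = self._initial_state()

    def _initial_state(self) -> SimState:
        base = baseline_pain(self.params, 0)
        return SimState(
            clock=0,
            day_index=1,
            pain=base,
            baseline_pain=base,
            mobility=mobility_factor(base, self.params.min_mobility),
        )

    # -- queries --------------------------------------------------------

    def _spec(self, med_id: str) -> MedicationSpec:
        try:
            return self.medications[med_id]
        except KeyError:
            raise ConfigurationError(f"unknown medication {med_id!r}") from None

    def tablets_in_effect(self, med_id: str) -> int:
        """Tablets of ``med_id`` whose elapsed time is in [onset, effect_duration)."""
        spec = self._spec(med_id)
        t = self.state.clock
        return sum(
            d.tablets
            for d in self.state.active_doses
            if d.med_id == med_id
            and spec.onset <= t - d.time_taken < spec.effect_duration
        )

    def total_relief(self, t: Optional[int] = None) -> float:
        """Uncapped summed relief over all active doses at time ``t``."""
        if t is None:
            t = self.state.clock
        return sum(
            dose_relief(d, self._spec(d.med_id), t)
            for d in self.state.active_doses
            if d.time_taken <= t
        )

    def applied_relief(self) -> float:
        """Relief actually entering the dynamics this step: capped, and
        zero while the pain is unmanageable (no response to medication)."""
        if self.state.unmanageable_active:
            return 0.0
        return min(self.params.relief_cap, self.total_relief())

    def activity_offset(self) -> float:
        t = self.state.clock
        return sum(a.magnitude for a in self.state.activity_effects if a.expiry > t)

    # -- actions --------------------------------------------------------

    def take_dose(self, med_id: str, tablets: int) -> bool:
        """Attempt a dose now. Limit violations are refused and logged,
        never simulated as overdose; returns whether the dose was taken."""
        spec = self._spec(med_id)
        if tablets < 1:
            raise ContractViolation("tablets must be >= 1")
        s = self.state
        reason = None
        if tablets > spec.max_tablets_per_dose:
            reason = "max_tablets_per_dose"
        elif s.tablets_today.get(med_id, 0) + tablets > spec.max_tablets_per_day:
            reason = "max_tablets_per_day"
        elif (
            med_id in s.last_dose_time
            and s.clock - s.last_dose_time[med_id] < spec.min_dose_interval
        ):
            reason = "min_dose_interval"
        if reason is not None:
            self.log.add(
                s.clock, "refusal",
                action="dose", med_id=med_id, tablets=tablets, reason=reason,
            )
            return False

        dose = DoseEvent(med_id=med_id, tablets=tablets, time_taken=s.clock)
        s.active_doses.append(dose)
        s.tablets_today[med_id] = s.tablets_today.get(med_id, 0) + tablets
        s.last_dose_time[med_id] = s.clock
        self.log.add(s.clock, "dose", med_id=med_id, tablets=tablets)
        self._evaluate_side_effects(spec)
        return True

    def can_take(self, med_id: str, tablets: int) -> bool:
        """Dry-run of the take_dose guards."""
        spec = self._spec(med_id)
        s = self.state
        return (
            1 <= tablets <= spec.max_tablets_per_dose
            and s.tablets_today.get(med_id, 0) + tablets <= spec.max_tablets_per_day
            and (
                med_id not in s.last_dose_time
                or s.clock - s.last_dose_time[med_id] >= spec.min_dose_interval
            )
        )

    def _trigger_metric(self, spec: MedicationSpec, metric: str) -> int:
        s = self.state
        if metric == "daily_tablets":
            return s.tablets_today.get(spec.id, 0)
        # active_tablets: any dose not yet worn off, the just-taken one included
        return sum(
            d.tablets
            for d in s.active_doses
            if d.med_id == spec.id
            and s.clock - d.time_taken < spec.effect_duration
        )

    def _evaluate_side_effects(self, spec: MedicationSpec) -> None:
        s = self.state
        for rule in spec.side_effect_rules:
            if self._trigger_metric(spec, rule.metric) >= rule.threshold:
                expiry = s.clock + rule.duration
                already = s.active_side_effects.get(rule.effect_id)
                if already is None:
                    s.active_side_effects[rule.effect_id] = expiry
                    self.log.add(
                        s.clock, "side_effect_onset",
                        effect_id=rule.effect_id, source=spec.id,
                    )
                else:
                    # re-trigger extends an active effect, no new onset entry
                    s.active_side_effects[rule.effect_id] = max(already, expiry)

    def add_activity_effect(self, magnitude: float, expiry: int) -> None:
        self.state.activity_effects.append(
            ActivityEffect(magnitude=magnitude, expiry=expiry)
        )

    # -- dynamics -------------------------------------------------------

    def step(self) -> SimState:
        """Advance the clock by ``dt`` and update pain, expiries, mobility."""
        s, p = self.state, self.params
        s.clock += p.dt

        new_day = s.clock // MINUTES_PER_DAY + 1
        if new_day != s.day_index:
            s.day_index = new_day
            s.tablets_today = {}

        # expire worn-off doses (hygiene; they contribute zero relief anyway)
        s.active_doses = [
            d
            for d in s.active_doses
            if s.clock - d.time_taken < self._spec(d.med_id).effect_duration
        ]
        for eid, expiry in list(s.active_side_effects.items()):
            if s.clock >= expiry:
                del s.active_side_effects[eid]
                self.log.add(s.clock, "side_effect_end", effect_id=eid)
        s.activity_effects = [a for a in s.activity_effects if a.expiry > s.clock]

        s.baseline_pain = baseline_pain(p, s.clock)
        target = s.baseline_pain - self.applied_relief() + self.activity_offset()
        target = min(10.0, max(0.0, target))
        alpha = 1.0 - math.exp(-p.relaxation_rate * p.dt)
        s.pain += alpha * (target - s.pain)
        s.pain = min(10.0, max(0.0, s.pain))
        if s.unmanageable_active:
            s.pain = max(s.pain, self.pain_floor)
        s.mobility = mobility_factor(s.pain, p.min_mobility)

        self.log.add(
            s.clock, "pain_sample",
            pain=s.pain,
            relief=self.applied_relief(),
            side_effects=sorted(s.active_side_effects),
        )
        return s
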