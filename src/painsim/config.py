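"""Loading and validation of configuration files.

Every numeric game constant lives in JSON config, not in code. The
package bundles defaults under ``painsim/data/``; any file can be
overridden by pointing the loaders (or the CLI ``--config-dir``) at a
directory containing files of the same names.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Optional

from .errors import ConfigurationError
from .instruments import InstrumentSpec, instrument_from_dict
from .session import (
    DayGoal,
    GameConfig,
    MonologueConfig,
    UnmanageableEventConfig,
)
from .simulation_core import MedicationSpec, PainModelParams, SideEffectRule
from .world import Activity

_DATA = resources.files("painsim") / "data"

BUNDLED_INSTRUMENTS = ("attrakdiff2", "pop_mgs", "bq2", "pak_ppm")


def _read_json(name: str, config_dir: Optional[str | Path]) -> dict[str, Any]:
    if config_dir is not None:
        path = Path(config_dir) / name
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
    else:
        try:
            text = (_DATA / name).read_text()
        except FileNotFoundError:
            raise ConfigurationError(f"bundled config missing: {name}") from None
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{name}: invalid JSON ({exc})") from None


def load_medications(config_dir: Optional[str | Path] = None) -> dict[str, MedicationSpec]:
    raw = _read_json("medications.json", config_dir)
    meds = {}
    try:
        for m in raw["medications"]:
            rules = tuple(
                SideEffectRule(
                    effect_id=r["effect_id"],
                    metric=r["metric"],
                    threshold=int(r["threshold"]),
                    duration=int(r["duration"]),
                )
                for r in m.get("side_effect_rules", [])
            )
            spec = MedicationSpec(
                id=m["id"],
                tablet_strength=m["tablet_strength"],
                max_tablets_per_dose=int(m["max_tablets_per_dose"]),
                max_tablets_per_day=int(m["max_tablets_per_day"]),
                min_dose_interval=int(m["min_dose_interval"]),
                onset=int(m["onset"]),
                time_to_peak=int(m["time_to_peak"]),
                effect_duration=int(m["effect_duration"]),
                peak_relief=float(m["peak_relief"]),
                side_effect_rules=rules,
            )
            meds[spec.id] = spec
    except KeyError as exc:
        raise ConfigurationError(f"medications.json: missing field {exc}") from None
    if not meds:
        raise ConfigurationError("medications.json defines no medications")
    return meds


def load_model_params(config_dir: Optional[str | Path] = None) -> PainModelParams:
    raw = _read_json("model_params.json", config_dir)
    try:
        curve = {
            int(day): [(float(h), float(v)) for h, v in anchors]
            for day, anchors in raw["baseline_curve"].items()
        }
        return PainModelParams(
            baseline_curve=curve,
            relief_cap=float(raw["relief_cap"]),
            relaxation_rate=float(raw["relaxation_rate"]),
            dt=int(raw["dt"]),
            min_mobility=float(raw["min_mobility"]),
            immobility_threshold=float(raw["immobility_threshold"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"model_params.json: missing field {exc}") from None


def load_activities(config_dir: Optional[str | Path] = None) -> dict[str, Activity]:
    raw = _read_json("activities.json", config_dir)
    acts = {}
    try:
        for a in raw["activities"]:
            act = Activity(
                id=a["id"],
                kind=a["kind"],
                duration=int(a["duration"]),
                pain_effect=float(a["pain_effect"]),
                requires_movement=bool(a["requires_movement"]),
                counts_toward_tasks=bool(a["counts_toward_tasks"]),
            )
            acts[act.id] = act
    except KeyError as exc:
        raise ConfigurationError(f"activities.json: missing field {exc}") from None
    return acts


def load_tasks(config_dir: Optional[str | Path] = None) -> dict[int, list[str]]:
    raw = _read_json("tasks.json", config_dir)
    try:
        return {int(d): list(ids) for d, ids in raw["tasks_by_day"].items()}
    except KeyError as exc:
        raise ConfigurationError(f"tasks.json: missing field {exc}") from None


def load_goals(
    config_dir: Optional[str | Path] = None,
) -> tuple[dict[int, DayGoal], dict[str, Any]]:
    raw = _read_json("goals.json", config_dir)
    try:
        goals = {}
        for g in raw["goals"]:
            goal = DayGoal(
                day_index=int(g["day_index"]),
                kind=g["kind"],
                threshold=g.get("threshold"),
                description=g.get("description", ""),
            )
            goals[goal.day_index] = goal
        return goals, raw
    except KeyError as exc:
        raise ConfigurationError(f"goals.json: missing field {exc}") from None


def load_game_config(config_dir: Optional[str | Path] = None) -> GameConfig:
    """Assemble the full game configuration, cross-validating references."""
    meds = load_medications(config_dir)
    params = load_model_params(config_dir)
    activities = load_activities(config_dir)
    tasks = load_tasks(config_dir)
    goals, raw_goals = load_goals(config_dir)

    for day, ids in tasks.items():
        for act_id in ids:
            if act_id not in activities:
                raise ConfigurationError(
                    f"tasks.json: day {day} references unknown activity {act_id!r}"
                )

    ev = raw_goals.get("event", {})
    mono = raw_goals.get("monologue", {})
    star = raw_goals.get("star_thresholds", {})
    return GameConfig(
        medications=meds,
        params=params,
        activities=activities,
        tasks_by_day=tasks,
        goals=goals,
        event=UnmanageableEventConfig(
            probability=float(ev.get("probability", 0.3)),
            pain_floor=float(ev.get("pain_floor", 8.0)),
            post_consult_pain=float(ev.get("post_consult_pain", 5.0)),
        ),
        monologue=MonologueConfig(
            flavor_rate=float(mono.get("flavor_rate", 0.02)),
            pain_thresholds=tuple(mono.get("pain_thresholds", (3.0, 5.0, 8.0))),
            flavor_messages=tuple(mono.get("flavor_messages", ("...",))),
            medication_working=mono.get(
                "medication_working", "I can feel the medication working..."
            ),
            pain_rising=mono.get("pain_rising", "My pain is getting worse."),
            pain_easing=mono.get("pain_easing", "The pain is easing off."),
        ),
        star_threshold_three=float(star.get("three", 0.95)),
        star_threshold_two=float(star.get("two", 0.6)),
        dose_ceiling=int(raw_goals.get("dose_ceiling", 8)),
    )


def load_instrument(name_or_path: str) -> InstrumentSpec:
    """Load a bundled instrument by name, or any definition by path."""
    if name_or_path in BUNDLED_INSTRUMENTS:
        text = (_DATA / "instruments" / f"{name_or_path}.json").read_text()
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ConfigurationError(
                f"unknown instrument {name_or_path!r} "
                f"(bundled: {', '.join(BUNDLED_INSTRUMENTS)})"
            )
        text = path.read_text()
    return instrument_from_dict(json.loads(text))
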