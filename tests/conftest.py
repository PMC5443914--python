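import dataclasses

import pytest

from painsim.config import load_game_config, load_instrument
from painsim.simulation_core import Engine
from painsim.telemetry import TelemetryLog


@pytest.fixture(scope="session")
def cfg():
    return load_game_config()


@pytest.fixture(scope="session")
def meds(cfg):
    return cfg.medications


@pytest.fixture(scope="session")
def params(cfg):
    return cfg.params


@pytest.fixture()
def engine(cfg):
    return Engine(cfg.medications, cfg.params, pain_floor=cfg.event.pain_floor)


@pytest.fixture(scope="session")
def attrakdiff_spec():
    return load_instrument("attrakdiff2")


@pytest.fixture(scope="session")
def pak_spec():
    return load_instrument("pak_ppm")


@pytest.fixture(scope="session")
def bq2_spec():
    return load_instrument("bq2")


@pytest.fixture(scope="session")
def popmgs_spec():
    return load_instrument("pop_mgs")


def cfg_with(cfg, probability=None, flavor_rate=None):
    """Shallow config copy with the event probability and/or flavor rate changed."""
    new = dataclasses.replace(cfg)
    if probability is not None:
        new.event = dataclasses.replace(cfg.event, probability=probability)
    if flavor_rate is not None:
        new.monologue = dataclasses.replace(cfg.monologue, flavor_rate=flavor_rate)
    return new


@pytest.fixture()
def quiet_cfg(cfg):
    """Config with unmanageable events and flavor monologue disabled."""
    return cfg_with(cfg, probability=0.0, flavor_rate=0.0)


def constant_pain_log(pain, params, day_index=1, tablets=0, med_id="paracetamol"):
    """Synthetic complete day log pinned at a constant pain level."""
    log = TelemetryLog()
    start = (day_index - 1) * 1440
    taken = 0
    while taken < tablets:
        take = min(2, tablets - taken)
        log.add(start, "dose", med_id=med_id, tablets=take)
        taken += take
    for i in range(1, params.steps_per_day + 1):
        log.add(start + i * params.dt, "pain_sample",
                pain=float(pain), relief=0.0, side_effects=[])
    return log


def random_day_log(rng, params, day_index=1):
    """Synthetic complete day log with random pain samples and doses."""
    log = TelemetryLog()
    start = (day_index - 1) * 1440
    for _ in range(int(rng.integers(0, 5))):
        log.add(start, "dose", med_id="paracetamol", tablets=int(rng.integers(1, 3)))
    for i in range(1, params.steps_per_day + 1):
        log.add(start + i * params.dt, "pain_sample",
                pain=float(rng.uniform(0, 10)), relief=0.0, side_effects=[])
    return log
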