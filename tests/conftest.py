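import dataclasses

import pytest

from rtsim.population import Patient, ZERO_RATES, CovidRates
from rtsim.scenarios import Roster, ScenarioConfig, SimParameters


ZERO_DISTANCES = {key: 0.0 for key in SimParameters().distances}


def toy_params(**overrides) -> SimParameters:
    """Parameters with zero walking distances so traces are hand-computable."""
    base = dict(distances=dict(ZERO_DISTANCES))
    base.update(overrides)
    return dataclasses.replace(SimParameters(), **base)


def custom_scenario(
    roster: Roster = None,
    screening: bool = False,
    rates: CovidRates = ZERO_RATES,
    params: SimParameters = None,
    category: int = 1,
) -> ScenarioConfig:
    return ScenarioConfig(
        scenario_id=None,
        category=category,
        shortfall="custom",
        roster=roster or Roster(),
        covid_rates=rates,
        screening_enabled=screening,
        params=params or toy_params(),
    )


def make_patient(
    patient_id=0,
    pathway="follow_up_fraction",
    arrival=0.0,
    service=10.0,
    checkin=1.0,
    covid="none",
    speed=60.0,
    age=60.0,
) -> Patient:
    return Patient(
        patient_id=patient_id,
        age=age,
        gender="female",
        pathway=pathway,
        covid_status=covid,
        scheduled_arrival=arrival,
        walking_speed=speed,
        stream="test",
        service_time=service,
        checkin_time=checkin,
        fever=covid == "new",
    )


def assert_fifo_audit(grant_log):
    """Among non-priority requests with identical demands, grants never
    invert request order."""
    by_signature = {}
    for entry in grant_log:
        if entry["priority"]:
            continue
        sig = tuple(sorted(entry["demands"].items()))
        by_signature.setdefault(sig, []).append(entry)
    for entries in by_signature.values():
        entries.sort(key=lambda e: e["request_seq"])
        grant_times = [e["grant_time"] for e in entries]
        assert grant_times == sorted(grant_times)


@pytest.fixture
def plain_roster():
    """Full-strength roster with everyone available all day."""
    return Roster(oncologists=2, oncologist_availability=1.0)
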