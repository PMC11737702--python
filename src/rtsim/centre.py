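"""Process model of one day in the radiotherapy centre.

A patient's visit is: arrival → (entrance protection measures, if enabled) →
check-in at the reception → waiting room → treatment with the pathway's
resource team → exit.  Resource demands per pathway:

===================  =============================================
consultation          1 radiation oncologist
final examination     1 radiation oncologist
aftercare             1 radiation oncologist
planning CT           1 CT + 2 RTTs
first fraction        1 LINAC + 2 RTTs + 1 oncologist + 1 physicist
follow-up fraction    1 LINAC + 2 RTTs
===================  =============================================

Rules of the day:

* Arrivals after closing (18:00, minute 600) are not admitted.
* A patient whose pathway needs a resource with zero configured capacity is
  sent home at arrival.
* Entrance measures (mask + temperature, plus a 15-minute rapid test when the
  fever rule triggers) occupy one administrator; patients already known to be
  COVID-19 positive bypass them entirely.
* A first-fraction patient first queues for the oncologist; once the
  oncologist is granted, the request for the remaining team jumps to the head
  of the queue (preferential allocation).  Queues are never preempted.
* Treatment of any COVID-19-positive patient blocks its resources for an
  extra 30 minutes (protective equipment, disinfection, ventilation).
* Treatments are never interrupted once started, but whoever has not left by
  the end of the 30-minute grace period (minute 630) counts as unseen.
* The one-way walk from the waiting room to the treatment room happens with
  the team already seized (staff receive the patient in the room); the walk
  out is after release.  Walks accrue to moving time, never to waiting time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .engine import Delay, Engine, ResourceManager, Seize
from .kpis import DayResult
from .population import Patient, generate_daily_patients
from .scenarios import ScenarioConfig, TREATMENT_ROOMS, build_pools


@dataclass(frozen=True)
class ProcessDefinition:
    pathway: str
    resource_demands: Dict[str, int]
    room: str


PROCESS_DEFINITIONS: Dict[str, ProcessDefinition] = {
    "consultation": ProcessDefinition(
        "consultation", {"oncologist": 1}, "consultation_room"
    ),
    "final_exam": ProcessDefinition(
        "final_exam", {"oncologist": 1}, "consultation_room"
    ),
    "aftercare": ProcessDefinition(
        "aftercare", {"oncologist": 1}, "consultation_room"
    ),
    "plan_ct": ProcessDefinition("plan_ct", {"ct": 1, "rtt": 2}, "ct_room"),
    "first_fraction": ProcessDefinition(
        "first_fraction",
        {"linac": 1, "rtt": 2, "oncologist": 1, "physicist": 1},
        "linac_room",
    ),
    "follow_up_fraction": ProcessDefinition(
        "follow_up_fraction", {"linac": 1, "rtt": 2}, "linac_room"
    ),
}


def travel_time(
    patient: Patient, from_room: str, to_room: str, distances: Dict
) -> float:
    """Walking minutes between two rooms at the patient's age-banded speed."""
    if from_room == to_room:
        return 0.0
    d = distances.get((from_room, to_room), distances.get((to_room, from_room)))
    if d is None:
        raise ValueError(f"unknown room pair {from_room!r} -> {to_room!r}")
    return d / patient.walking_speed


def screening_duration(patient: Patient, params) -> float:
    """Administrator occupancy for the entrance protection measures."""
    duration = params.mask_time + params.temperature_time
    if patient.fever:
        duration += params.rapid_test_time
    return duration


def _visit(
    patient: Patient,
    scenario: ScenarioConfig,
    engine: Engine,
    manager: ResourceManager,
):
    params = scenario.params
    defn = PROCESS_DEFINITIONS[patient.pathway]
    patient.trace["arrival"] = engine.now

    walk = travel_time(patient, "entrance", "reception", params.distances)
    yield Delay(walk)
    patient.moving_time += walk

    if scenario.screening_enabled and patient.covid_status != "known":
        grant = yield Seize(
            manager, {"administrator": 1}, tag="screening", owner=patient.patient_id
        )
        patient.waits["screening"] = grant.wait
        patient.trace["screening_start"] = engine.now
        duration = screening_duration(patient, params)
        yield Delay(duration)
        grant.release()
        patient.trace["screening_end"] = engine.now
        patient.process_time += duration

    grant = yield Seize(
        manager, {"administrator": 1}, tag="checkin", owner=patient.patient_id
    )
    patient.waits["checkin"] = grant.wait
    patient.trace["checkin_start"] = engine.now
    yield Delay(patient.checkin_time)
    grant.release()
    patient.trace["checkin_end"] = engine.now
    patient.process_time += patient.checkin_time

    walk = travel_time(patient, "reception", "waiting_room", params.distances)
    yield Delay(walk)
    patient.moving_time += walk

    if patient.pathway == "first_fraction":
        # queue for the scarce oncologist first; with the oncologist in hand
        # the rest of the team is allocated preferentially
        onc_grant = yield Seize(
            manager, {"oncologist": 1}, tag="treatment", owner=patient.patient_id
        )
        team = {k: v for k, v in defn.resource_demands.items() if k != "oncologist"}
        team_grant = yield Seize(
            manager, team, priority=True, tag="treatment", owner=patient.patient_id
        )
        grants = [onc_grant, team_grant]
        patient.waits["treatment"] = onc_grant.wait + team_grant.wait
    else:
        grant = yield Seize(
            manager,
            defn.resource_demands,
            tag="treatment",
            owner=patient.patient_id,
        )
        grants = [grant]
        patient.waits["treatment"] = grant.wait

    walk = travel_time(patient, "waiting_room", defn.room, params.distances)
    yield Delay(walk)
    patient.moving_time += walk
    patient.trace["treatment_start"] = engine.now

    service = patient.service_time
    if patient.covid_status != "none":
        service += params.covid_treatment_extension
    yield Delay(service)
    for g in grants:
        g.release()
    patient.trace["treatment_end"] = engine.now
    patient.process_time += service

    walk = travel_time(patient, defn.room, "exit", params.distances)
    yield Delay(walk)
    patient.moving_time += walk
    patient.trace["exit"] = engine.now
    patient.outcome = "treated"


def _mark_unseen(patient: Patient, reason: str, time: Optional[float] = None) -> None:
    patient.outcome = "unseen"
    patient.unseen_reason = reason
    if time is not None:
        patient.trace.setdefault("arrival", time)
        patient.trace["exit"] = time


def run_day(
    scenario: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    patients: Optional[List[Patient]] = None,
) -> DayResult:
    """Simulate one day and return its :class:`DayResult`.

    ``patients`` may be supplied directly (e.g. hand-built traces in tests);
    otherwise the population is generated from ``rng``.
    """
    if patients is None:
        if rng is None:
            raise ValueError("need an rng when patients are not supplied")
        patients = generate_daily_patients(scenario, rng)

    params = scenario.params
    engine = Engine(horizon=params.horizon)
    manager = ResourceManager(engine, build_pools(scenario))
    by_id = {p.patient_id: p for p in patients}

    for patient in patients:
        defn = PROCESS_DEFINITIONS[patient.pathway]
        if patient.scheduled_arrival > params.closing:
            _mark_unseen(patient, "after_hours", patient.scheduled_arrival)
            continue
        needed = dict(defn.resource_demands)
        needed["administrator"] = 1
        unservable = any(
            manager.pools[name].capacity < n for name, n in needed.items()
        )
        if unservable:
            # sent home at the door: the day's roster can never serve them
            _mark_unseen(patient, "no_resources", patient.scheduled_arrival)
            continue
        engine.schedule(
            patient.scheduled_arrival,
            (lambda p: lambda: engine.launch(_visit(p, scenario, engine, manager)))(
                patient
            ),
        )

    engine.run()

    # accrue queueing time of requests still pending at the grace-period end
    for req in manager.pending:
        if req.owner is not None and req.owner in by_id:
            by_id[req.owner].waits[req.tag] += params.horizon - req.request_time
    manager.finalize()
    for patient in patients:
        if patient.outcome is None:
            _mark_unseen(patient, "closing")

    return DayResult(
        patients=patients,
        pool_busy=manager.busy_summary(),
        pool_available={
            name: pool.scheduled_minutes() for name, pool in manager.pools.items()
        },
        grant_log=manager.grant_log,
    )
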