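"""Synthetic daily patient population.

Each replication simulates one business day of a stand-alone radiotherapy
centre.  All randomness of a replication lives here: every patient is created
at day start with their pathway, arrival time, demographics, COVID-19 status
and pre-drawn service durations, so that the downstream process model is a
deterministic function of the generated population.  This also makes common
random numbers across resource scenarios exact: two scenarios in the same
COVID-19 category see bitwise-identical patient populations for the same seed.

Arrival streams
---------------
* two follow-up irradiation streams (one per LINAC slot plan), 60 patients
  each, interarrival uniform(8, 12) min,
* one planning-CT stream, 10 patients, interarrival uniform(25, 35) min,
* one radiation-oncologist appointment stream, 16 patients, with a fixed
  multinomial type mix over consultation, first fraction, final examination
  and aftercare.

Patients known to be COVID-19 positive before the visit are scheduled with an
extra 30 minutes, which shifts every later arrival of their stream by
+30 min; newly positive patients are unplanned disruptions and shift nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

#: Destatis/RKI reference population of Germany used for incidence and
#: prevalence rates at the reference dates (31.12.2020 census update).
REFERENCE_POPULATION = 83_166_711

PATHWAYS = (
    "consultation",
    "plan_ct",
    "first_fraction",
    "follow_up_fraction",
    "final_exam",
    "aftercare",
)

#: pathways booked through the radiation-oncologist appointment stream
ONCOLOGIST_PATHWAYS = ("consultation", "first_fraction", "final_exam", "aftercare")

COVID_STATUSES = ("none", "known", "new")


@dataclass(frozen=True)
class CovidRates:
    """Per-patient probabilities of being a new- or known-COVID-19 patient.

    ``rate_new`` derives from the one-day incidence, ``rate_known`` from the
    prevalence minus that day's new infections.
    """

    rate_new: float
    rate_known: float

    def __post_init__(self) -> None:
        if self.rate_new < 0 or self.rate_known < 0:
            raise ValueError("COVID-19 rates must be non-negative")
        if self.rate_new + self.rate_known > 1:
            raise ValueError("COVID-19 rates must sum to at most 1")


ZERO_RATES = CovidRates(0.0, 0.0)


def derive_covid_rates(
    new_cases: int,
    active_cases: int,
    population: int = REFERENCE_POPULATION,
) -> CovidRates:
    """Convert a day's case counts into per-patient probabilities.

    ``rate_new = new_cases / population`` (one-day incidence) and
    ``rate_known = (active_cases - new_cases) / population`` (prevalence
    excluding patients who only turned positive that day).  Rounding is left
    to display code.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= new_cases <= active_cases <= population:
        raise ValueError(
            "expected 0 <= new_cases <= active_cases <= population, got "
            f"{new_cases}, {active_cases}, {population}"
        )
    return CovidRates(
        rate_new=new_cases / population,
        rate_known=(active_cases - new_cases) / population,
    )


@dataclass
class Patient:
    """One simulated person and, after the day has run, their visit record."""

    patient_id: int
    age: float
    gender: str
    pathway: str
    covid_status: str
    scheduled_arrival: float
    walking_speed: float  # metres / minute, age-banded
    stream: str
    service_time: float
    checkin_time: float
    fever: bool
    # filled in by the centre process model
    trace: Dict[str, float] = field(default_factory=dict)
    waits: Dict[str, float] = field(
        default_factory=lambda: {"screening": 0.0, "checkin": 0.0, "treatment": 0.0}
    )
    process_time: float = 0.0
    moving_time: float = 0.0
    outcome: Optional[str] = None  # "treated" | "unseen"
    unseen_reason: Optional[str] = None

    @property
    def total_wait(self) -> float:
        return sum(self.waits.values())

    @property
    def admitted(self) -> bool:
        """Entered the centre (was not turned away at the door)."""
        return self.outcome == "treated" or self.unseen_reason == "closing"


def sample_service_time(activity: str, rng: np.random.Generator, distributions=None) -> float:
    """Draw one service duration in minutes for ``activity``.

    ``distributions`` maps activity labels to distribution specs,
    ``("uniform", lo, hi)`` or ``("triangular", lo, mode, hi)``; when omitted
    the packaged defaults are used.
    """
    if distributions is None:
        from .scenarios import DEFAULT_SERVICE_DISTRIBUTIONS

        distributions = DEFAULT_SERVICE_DISTRIBUTIONS
    try:
        spec = distributions[activity]
    except KeyError:
        raise ValueError(f"unknown activity label {activity!r}") from None
    return sample_distribution(spec, rng)


def sample_distribution(spec, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "uniform":
        _, lo, hi = spec
        return float(rng.uniform(lo, hi))
    if kind == "triangular":
        _, lo, mode, hi = spec
        return float(rng.triangular(lo, mode, hi))
    raise ValueError(f"unknown distribution kind {spec[0]!r}")


def _draw_covid_status(rates: CovidRates, rng: np.random.Generator, n: int) -> List[str]:
    u = rng.random(n)
    out = []
    for x in u:
        if x < rates.rate_new:
            out.append("new")
        elif x < rates.rate_new + rates.rate_known:
            out.append("known")
        else:
            out.append("none")
    return out


def _sample_age(params, rng: np.random.Generator) -> float:
    bands = params.age_bands
    weights = np.array([w for _, _, w in bands], dtype=float)
    idx = rng.choice(len(bands), p=weights / weights.sum())
    lo, hi, _ = bands[idx]
    return float(rng.uniform(lo, hi))


def _walking_speed(age: float, params) -> float:
    for limit, speed in params.walking_speed_bands:
        if age < limit:
            return speed
    return params.walking_speed_bands[-1][1]


def generate_daily_patients(scenario, rng: np.random.Generator) -> List[Patient]:
    """Build one day's patient population for ``scenario``.

    Returns patients sorted by scheduled arrival.  Patients scheduled past
    closing are still generated (they count as generated-but-unseen once the
    day runs).  The draw order is fixed — per-stream gaps, appointment types,
    COVID-19 statuses, demographics, service durations — so a seed fully
    determines the population.
    """
    params = scenario.params
    rates = scenario.covid_rates

    streams: List[tuple] = []  # (stream label, pathway, arrival)
    # follow-up streams, one per planned LINAC slot sequence
    for label, n in (("follow_up_a", params.n_follow_up_per_stream),
                     ("follow_up_b", params.n_follow_up_per_stream)):
        gaps = rng.uniform(*params.follow_up_interarrival, size=n)
        for t in np.cumsum(gaps):
            streams.append((label, "follow_up_fraction", float(t)))
    gaps = rng.uniform(*params.plan_ct_interarrival, size=params.n_plan_ct)
    for t in np.cumsum(gaps):
        streams.append(("plan_ct", "plan_ct", float(t)))
    gaps = rng.uniform(*params.oncologist_interarrival, size=params.n_oncologist)
    onc_arrivals = np.cumsum(gaps)
    probs = np.array(params.oncologist_type_mix, dtype=float)
    types = rng.choice(ONCOLOGIST_PATHWAYS, size=params.n_oncologist,
                       p=probs / probs.sum())
    for t, pathway in zip(onc_arrivals, types):
        streams.append(("oncologist", str(pathway), float(t)))

    # COVID-19 status per patient, then the known-COVID schedule shift:
    # every patient after a known-positive in the same stream moves +30 min.
    statuses = _draw_covid_status(rates, rng, len(streams))
    by_stream: Dict[str, List[int]] = {}
    for i, (label, _, _) in enumerate(streams):
        by_stream.setdefault(label, []).append(i)
    arrivals = [t for _, _, t in streams]
    for label, idxs in by_stream.items():
        offset = 0.0
        for i in idxs:
            arrivals[i] += offset
            if statuses[i] == "known":
                offset += params.known_covid_slot_extension

    patients: List[Patient] = []
    for i, (label, pathway, _) in enumerate(streams):
        age = _sample_age(params, rng)
        gender = str(rng.choice(("female", "male")))
        service = sample_service_time(pathway, rng, params.service_distributions)
        checkin_spec = (
            params.checkin_consultation
            if pathway == "consultation"
            else params.checkin_other
        )
        checkin = sample_distribution(checkin_spec, rng)
        fever = statuses[i] == "new"
        if statuses[i] == "none" and params.fever_probability > 0:
            fever = bool(rng.random() < params.fever_probability)
        patients.append(
            Patient(
                patient_id=-1,
                age=age,
                gender=gender,
                pathway=pathway,
                covid_status=statuses[i],
                scheduled_arrival=arrivals[i],
                walking_speed=_walking_speed(age, params),
                stream=label,
                service_time=service,
                checkin_time=checkin,
                fever=fever,
            )
        )

    patients.sort(key=lambda p: p.scheduled_arrival)
    for pid, p in enumerate(patients):
        p.patient_id = pid
    return patients


def population_frame(patients: List[Patient]):
    """Per-patient audit table (one row per patient) as a DataFrame."""
    import pandas as pd

    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "pathway": p.pathway,
                "stream": p.stream,
                "age": p.age,
                "gender": p.gender,
                "covid_status": p.covid_status,
                "scheduled_arrival": p.scheduled_arrival,
                "outcome": p.outcome,
                "unseen_reason": p.unseen_reason,
                "wait_screening": p.waits["screening"],
                "wait_checkin": p.waits["checkin"],
                "wait_treatment": p.waits["treatment"],
                "total_wait": p.total_wait,
                "process_time": p.process_time,
                "moving_time": p.moving_time,
                "exit_time": p.trace.get("exit"),
            }
        )
    return pd.DataFrame(rows)
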