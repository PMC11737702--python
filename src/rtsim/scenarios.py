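"""The experimental grid: rosters, COVID-19 categories and the 21 scenarios.

The study design crosses seven resource configurations (full roster plus six
shortfalls) with three COVID-19 categories:

* category 1 — no protection measures, no COVID-19 patients,
* category 2 — entrance protection measures, low incidence/prevalence
  (Germany, 22.10.2021),
* category 3 — entrance protection measures, high incidence/prevalence
  (Germany, 25.03.2022).

Scenario ids 0-20 enumerate the grid column-major: ids 0-6 are category 1,
7-13 category 2, 14-20 category 3, in the shortfall order
(none, -1 oncologist, -2 RTT, -4 RTT, -1 administrator,
-1 oncologist -2 RTT -1 administrator, -1 LINAC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .population import CovidRates, ZERO_RATES, derive_covid_rates
from .engine import Pool, Unit

HORIZON = 630.0  # 10-hour day + 30-minute grace period, minutes
CLOSING = 600.0  # 18:00; arrivals after this are not admitted

#: Table of daily case counts behind the low/high COVID-19 phases.
LOW_COVID_CASES = {"new_cases": 19_572, "active_cases": 150_200}
HIGH_COVID_CASES = {"new_cases": 296_498, "active_cases": 4_246_200}

DEFAULT_SERVICE_DISTRIBUTIONS = {
    # ranges and modes as elicited from practitioners; families are the
    # simplest consistent choice and are config-overridable
    "consultation": ("uniform", 20.0, 60.0),
    "plan_ct": ("uniform", 10.0, 20.0),
    "first_fraction": ("triangular", 10.0, 15.0, 20.0),
    "follow_up_fraction": ("triangular", 3.0, 7.0, 10.0),
    "final_exam": ("uniform", 10.0, 20.0),
    "aftercare": ("uniform", 10.0, 20.0),
}

#: room each pathway is treated in, for the travel model
TREATMENT_ROOMS = {
    "consultation": "consultation_room",
    "final_exam": "consultation_room",
    "aftercare": "consultation_room",
    "plan_ct": "ct_room",
    "first_fraction": "linac_room",
    "follow_up_fraction": "linac_room",
}

#: one-way walking distances in metres, read off a floor plan with the
#: LINAC bunkers at the far end of the corridor
DEFAULT_DISTANCES = {
    ("entrance", "reception"): 15.0,
    ("reception", "waiting_room"): 10.0,
    ("waiting_room", "linac_room"): 70.0,
    ("waiting_room", "ct_room"): 50.0,
    ("waiting_room", "consultation_room"): 25.0,
    ("linac_room", "exit"): 80.0,
    ("ct_room", "exit"): 60.0,
    ("consultation_room", "exit"): 35.0,
}


@dataclass(frozen=True)
class SimParameters:
    """Everything tunable about one simulated day except the roster/rates."""

    horizon: float = HORIZON
    closing: float = CLOSING
    # arrival streams
    n_follow_up_per_stream: int = 60
    follow_up_interarrival: Tuple[float, float] = (8.0, 12.0)   # "10±2"
    n_plan_ct: int = 10
    plan_ct_interarrival: Tuple[float, float] = (25.0, 35.0)    # "30±5"
    n_oncologist: int = 16
    oncologist_interarrival: Tuple[float, float] = (30.0, 45.0)
    #: consultation, first fraction, final exam, aftercare
    oncologist_type_mix: Tuple[float, ...] = (9.0, 2.5, 2.4, 2.1)
    # service times
    service_distributions: Dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_SERVICE_DISTRIBUTIONS)
    )
    checkin_consultation: tuple = ("uniform", 4.0, 6.0)
    checkin_other: tuple = ("uniform", 1.0, 3.0)
    # entrance protection measures
    mask_time: float = 1.0
    temperature_time: float = 1.0
    rapid_test_time: float = 15.0
    fever_probability: float = 0.0  # extra fever rate among non-COVID patients
    # COVID-19 handling
    covid_treatment_extension: float = 30.0
    known_covid_slot_extension: float = 30.0
    # demographics: (lo, hi, weight) age bands, coarse adult cancer-age shape
    age_bands: Tuple[Tuple[float, float, float], ...] = (
        (40.0, 50.0, 0.10),
        (50.0, 60.0, 0.20),
        (60.0, 75.0, 0.45),
        (75.0, 90.0, 0.25),
    )
    #: (age upper bound, metres/minute); last entry is the open-ended band
    walking_speed_bands: Tuple[Tuple[float, float], ...] = (
        (65.0, 70.0),
        (75.0, 60.0),
        (float("inf"), 48.0),
    )
    # travel model
    distances: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCES)
    )


@dataclass(frozen=True)
class Roster:
    """Staff and equipment on the day, in heads/machines.

    The base establishment corresponds to 1.5 FTE radiation oncologists
    (two heads at 75% availability each), 6 RTTs, 2 administrators, a 0.1-FTE
    medical physicist (one head, used only for first fractions), two LINACs
    and one CT.
    """

    oncologists: int = 2
    oncologist_availability: float = 0.75
    rtts: int = 6
    administrators: int = 2
    physicists: int = 1
    linacs: int = 2
    cts: int = 1

    def __post_init__(self) -> None:
        for name in ("oncologists", "rtts", "administrators", "physicists",
                     "linacs", "cts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.oncologist_availability <= 1:
            raise ValueError("oncologist availability must be in (0, 1]")


#: shortfall label -> roster deltas (Table of experimental scenarios, rows)
SHORTFALLS: List[Tuple[str, Dict[str, int]]] = [
    ("none", {}),
    ("1 oncologist", {"oncologists": -1}),
    ("2 RTT", {"rtts": -2}),
    ("4 RTT", {"rtts": -4}),
    ("1 administrator", {"administrators": -1}),
    ("1 oncologist, 2 RTT, 1 administrator",
     {"oncologists": -1, "rtts": -2, "administrators": -1}),
    ("1 LINAC", {"linacs": -1}),
]

N_SCENARIOS = 21


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the experimental grid (or a custom configuration)."""

    scenario_id: Optional[int]
    category: int  # 1 | 2 | 3
    shortfall: str
    roster: Roster
    covid_rates: CovidRates
    screening_enabled: bool
    params: SimParameters = field(default_factory=SimParameters)

    @property
    def label(self) -> str:
        sid = "custom" if self.scenario_id is None else self.scenario_id
        return f"scenario {sid} (cat {self.category}, {self.shortfall})"


def category_settings(category: int) -> Tuple[bool, CovidRates]:
    """(screening enabled, COVID-19 rates) for a study category."""
    if category == 1:
        return False, ZERO_RATES
    if category == 2:
        return True, derive_covid_rates(**LOW_COVID_CASES)
    if category == 3:
        return True, derive_covid_rates(**HIGH_COVID_CASES)
    raise ValueError(f"unknown category {category}")


def apply_shortfall(roster: Roster, deltas: Dict[str, int]) -> Roster:
    changes = {name: getattr(roster, name) + d for name, d in deltas.items()}
    return replace(roster, **changes)


def build_scenario(scenario_id: int, params: Optional[SimParameters] = None) -> ScenarioConfig:
    """Expand a scenario id (0-20) into its full configuration."""
    if not 0 <= scenario_id < N_SCENARIOS:
        raise ValueError(f"scenario_id must be in 0..{N_SCENARIOS - 1}, got {scenario_id}")
    category = scenario_id // len(SHORTFALLS) + 1
    label, deltas = SHORTFALLS[scenario_id % len(SHORTFALLS)]
    screening, rates = category_settings(category)
    return ScenarioConfig(
        scenario_id=scenario_id,
        category=category,
        shortfall=label,
        roster=apply_shortfall(Roster(), deltas),
        covid_rates=rates,
        screening_enabled=screening,
        params=params or SimParameters(),
    )


def all_scenarios(params: Optional[SimParameters] = None) -> List[ScenarioConfig]:
    return [build_scenario(i, params) for i in range(N_SCENARIOS)]


def availability_windows(unit_index: int, fraction: float, horizon: float = HORIZON):
    """Deterministic on-duty windows for one staff unit.

    A unit at full availability works the whole staffed day ``(0, horizon)``.
    Partial availability removes a single contiguous off-block of length
    ``(1 - fraction) * horizon``, staggered so that even-indexed units are
    off at the start of the day and odd-indexed units at the end; with two
    75% oncologists at least one is on duty at all times.
    """
    if fraction <= 0:
        raise ValueError("availability fraction must be positive")
    if fraction > 1:
        raise ValueError("availability fraction cannot exceed 1")
    if fraction == 1:
        return [(0.0, horizon)]
    off = (1.0 - fraction) * horizon
    if unit_index % 2 == 0:
        return [(off, horizon)]
    return [(0.0, horizon - off)]


def build_pools(scenario: ScenarioConfig) -> Dict[str, Pool]:
    """Materialise the roster as engine resource pools."""
    horizon = scenario.params.horizon
    roster = scenario.roster
    full = [(0.0, horizon)]

    def units(n, windows=None):
        return [
            Unit(index=i, windows=windows(i) if callable(windows) else list(full))
            for i in range(n)
        ]

    onc_windows = lambda i: availability_windows(
        i, roster.oncologist_availability, horizon
    )
    return {
        "oncologist": Pool("oncologist", units(roster.oncologists, onc_windows)),
        "rtt": Pool("rtt", units(roster.rtts)),
        "administrator": Pool("administrator", units(roster.administrators)),
        "physicist": Pool("physicist", units(roster.physicists)),
        "linac": Pool("linac", units(roster.linacs)),
        "ct": Pool("ct", units(roster.cts)),
    }
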