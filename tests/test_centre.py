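"""Centre process model: screening, sent-home rules, traces, priorities."""

import dataclasses

import numpy as np
import pytest

from conftest import (
    assert_fifo_audit,
    custom_scenario,
    make_patient,
    toy_params,
)
from rtsim.centre import run_day, screening_duration, travel_time
from rtsim.population import CovidRates
from rtsim.scenarios import Roster, SimParameters, build_scenario


class TestTravel:
    def test_same_room_takes_no_time(self):
        p = make_patient(speed=60.0)
        assert travel_time(p, "waiting_room", "waiting_room", {}) == 0.0

    def test_distance_over_speed(self):
        p = make_patient(speed=60.0)
        assert travel_time(p, "a", "b", {("a", "b"): 60.0}) == pytest.approx(1.0)
        # table lookups are direction-agnostic
        assert travel_time(p, "b", "a", {("a", "b"): 60.0}) == pytest.approx(1.0)

    def test_unknown_room_pair_rejected(self):
        with pytest.raises(ValueError, match="unknown room pair"):
            travel_time(make_patient(), "a", "void", {})

    def test_default_distance_uses_age_banded_speed(self):
        params = SimParameters()
        p = make_patient(age=80.0, speed=48.0)
        expected = params.distances[("waiting_room", "linac_room")] / 48.0
        assert travel_time(p, "waiting_room", "linac_room", params.distances) == pytest.approx(expected)


class TestSingleVisit:
    def test_lone_patient_waits_zero(self):
        scenario = custom_scenario()
        p = make_patient(arrival=10.0, service=7.0, checkin=2.0)
        day = run_day(scenario, patients=[p])
        assert p.outcome == "treated"
        assert p.total_wait == 0.0
        assert p.trace["exit"] == pytest.approx(10.0 + 2.0 + 7.0)

    def test_travel_is_moving_time_not_waiting(self):
        scenario = custom_scenario(params=SimParameters())  # real distances
        p = make_patient(arrival=0.0, service=7.0, checkin=2.0, speed=60.0)
        day = run_day(scenario, patients=[p])
        d = scenario.params.distances
        expected_moving = (
            d[("entrance", "reception")]
            + d[("reception", "waiting_room")]
            + d[("waiting_room", "linac_room")]
            + d[("linac_room", "exit")]
        ) / 60.0
        assert p.total_wait == 0.0
        assert p.moving_time == pytest.approx(expected_moving)
        assert p.trace["exit"] == pytest.approx(2.0 + 7.0 + expected_moving)

    def test_arrival_after_closing_is_unseen(self):
        scenario = custom_scenario()
        p = make_patient(arrival=605.0)
        run_day(scenario, patients=[p])
        assert p.outcome == "unseen" and p.unseen_reason == "after_hours"

    def test_zero_capacity_resource_sends_patient_home(self):
        scenario = custom_scenario(roster=Roster(oncologists=0))
        p = make_patient(pathway="consultation", arrival=10.0)
        run_day(scenario, patients=[p])
        assert p.outcome == "unseen" and p.unseen_reason == "no_resources"

    def test_patient_still_inside_at_grace_end_is_unseen(self):
        scenario = custom_scenario()
        p = make_patient(arrival=599.0, service=60.0, checkin=1.0)
        run_day(scenario, patients=[p])
        assert p.outcome == "unseen" and p.unseen_reason == "closing"
        assert p.trace["treatment_start"] == pytest.approx(600.0)
        assert "exit" not in p.trace


class TestScreening:
    def test_screening_off_adds_nothing(self):
        scenario = custom_scenario(screening=False)
        p = make_patient(arrival=0.0)
        run_day(scenario, patients=[p])
        assert "screening_start" not in p.trace

    def test_plain_patient_occupies_administrator_two_minutes(self):
        scenario = custom_scenario(screening=True, rates=CovidRates(0.0, 0.01))
        p = make_patient(arrival=0.0, checkin=2.0)
        day = run_day(scenario, patients=[p])
        assert p.trace["screening_end"] - p.trace["screening_start"] == pytest.approx(2.0)
        assert day.pool_busy["administrator"] == pytest.approx(2.0 + 2.0)

    def test_new_covid_patient_takes_rapid_test(self):
        scenario = custom_scenario(screening=True, rates=CovidRates(0.01, 0.0))
        p = make_patient(arrival=0.0, covid="new", checkin=1.0)
        day = run_day(scenario, patients=[p])
        assert screening_duration(p, scenario.params) == pytest.approx(17.0)
        assert p.trace["screening_end"] - p.trace["screening_start"] == pytest.approx(17.0)
        # treatment blocked 30 extra minutes for protective measures
        assert p.trace["treatment_end"] - p.trace["treatment_start"] == pytest.approx(
            p.service_time + 30.0
        )

    def test_known_covid_patient_bypasses_screening_entirely(self):
        scenario = custom_scenario(screening=True, rates=CovidRates(0.0, 0.01))
        p = make_patient(arrival=0.0, covid="known")
        run_day(scenario, patients=[p])
        assert "screening_start" not in p.trace
        assert p.waits["screening"] == 0.0
        assert p.trace["treatment_end"] - p.trace["treatment_start"] == pytest.approx(
            p.service_time + 30.0
        )


class TestFivePatientHandTrace:
    """One administrator, one LINAC team: every timestamp matches the
    hand-computed trace exactly."""

    def test_trace(self):
        roster = Roster(
            oncologists=1, oncologist_availability=1.0, rtts=2,
            administrators=1, linacs=1,
        )
        scenario = custom_scenario(roster=roster)
        patients = [
            make_patient(patient_id=i, arrival=float(i), service=10.0, checkin=1.0)
            for i in range(5)
        ]
        day = run_day(scenario, patients=patients)
        # check-in: each granted on arrival (previous one releases just then)
        for i, p in enumerate(patients):
            assert p.trace["checkin_start"] == pytest.approx(float(i))
            assert p.trace["checkin_end"] == pytest.approx(float(i) + 1.0)
            assert p.waits["checkin"] == 0.0
        # single LINAC team: treatment starts 1, 11, 21, 31, 41
        starts = [p.trace["treatment_start"] for p in patients]
        assert starts == pytest.approx([1.0, 11.0, 21.0, 31.0, 41.0])
        waits = [p.waits["treatment"] for p in patients]
        assert waits == pytest.approx([0.0, 9.0, 18.0, 27.0, 36.0])
        exits = [p.trace["exit"] for p in patients]
        assert exits == pytest.approx([11.0, 21.0, 31.0, 41.0, 51.0])
        assert all(p.outcome == "treated" for p in patients)
        assert_fifo_audit(day.grant_log)


class TestPreferentialAllocation:
    def test_first_fraction_team_jumps_the_rtt_queue(self):
        roster = Roster(oncologists=2, oncologist_availability=1.0, rtts=2)
        scenario = custom_scenario(roster=roster)
        p0 = make_patient(patient_id=0, arrival=0.0, service=10.0)
        p1 = make_patient(patient_id=1, arrival=1.0, service=10.0)
        p2 = make_patient(
            patient_id=2, pathway="first_fraction", arrival=2.0, service=15.0
        )
        run_day(scenario, patients=[p0, p1, p2])
        # p1 queued for the RTT pair first, but the first-fraction team
        # request is allocated preferentially once the oncologist is held
        assert p2.trace["treatment_start"] == pytest.approx(11.0)
        assert p1.trace["treatment_start"] == pytest.approx(26.0)
        assert all(p.outcome == "treated" for p in (p0, p1, p2))

    def test_first_fraction_without_oncologist_cancelled_at_the_door(self):
        scenario = custom_scenario(roster=Roster(oncologists=0))
        p = make_patient(pathway="first_fraction", arrival=0.0)
        run_day(scenario, patients=[p])
        assert p.outcome == "unseen" and p.unseen_reason == "no_resources"

    def test_empty_centre_first_fraction_holds_all_five_units(self):
        scenario = custom_scenario(
            roster=Roster(oncologists=2, oncologist_availability=1.0)
        )
        p = make_patient(pathway="first_fraction", arrival=0.0, service=15.0, checkin=1.0)
        day = run_day(scenario, patients=[p])
        assert p.total_wait == 0.0
        assert day.pool_busy["linac"] == pytest.approx(15.0)
        assert day.pool_busy["rtt"] == pytest.approx(30.0)  # two RTTs
        assert day.pool_busy["physicist"] == pytest.approx(15.0)
        assert day.pool_busy["oncologist"] == pytest.approx(15.0)


class TestFullDayInvariants:
    @pytest.mark.parametrize("scenario_id", [0, 3, 11, 20])
    def test_conservation_and_trace_order(self, scenario_id):
        scenario = build_scenario(scenario_id)
        day = run_day(scenario, rng=np.random.default_rng(42))
        assert day.n_generated == day.n_treated + day.n_unseen
        order = [
            "arrival", "screening_start", "screening_end", "checkin_start",
            "checkin_end", "treatment_start", "treatment_end", "exit",
        ]
        for p in day.patients:
            times = [p.trace[k] for k in order if k in p.trace]
            assert times == sorted(times)
            assert all(w >= 0 for w in p.waits.values())
            if p.outcome == "treated":
                assert p.trace["exit"] <= scenario.params.horizon
        for pool, busy in day.pool_busy.items():
            assert 0.0 <= busy <= day.pool_available[pool] + 1e-9
        assert_fifo_audit(day.grant_log)

    def test_identical_seed_gives_identical_day(self):
        scenario = build_scenario(10)
        day_a = run_day(scenario, rng=np.random.default_rng(7))
        day_b = run_day(scenario, rng=np.random.default_rng(7))
        assert day_a.to_frame().equals(day_b.to_frame())

    def test_treatment_never_interrupted_by_availability_boundary(self):
        # the second 75% oncologist goes off duty at t=472.5; a consultation
        # started on that unit at t=458 still runs to completion
        roster = Roster(oncologists=2, oncologist_availability=0.75)
        scenario = custom_scenario(roster=roster)
        pa = make_patient(patient_id=0, pathway="consultation",
                          arrival=455.0, service=40.0, checkin=2.0)
        pb = make_patient(patient_id=1, pathway="consultation",
                          arrival=456.0, service=40.0, checkin=2.0)
        run_day(scenario, patients=[pa, pb])
        assert pb.trace["treatment_start"] == pytest.approx(458.0)
        assert pb.trace["treatment_end"] == pytest.approx(498.0)
        assert pb.outcome == "treated"

    def test_off_duty_oncologist_delays_early_consultation(self):
        # a single oncologist's off-block covers the start of the day
        roster = Roster(oncologists=1, oncologist_availability=0.75)
        scenario = custom_scenario(roster=roster)
        p = make_patient(pathway="consultation", arrival=10.0, service=30.0, checkin=2.0)
        run_day(scenario, patients=[p])
        assert p.trace["treatment_start"] == pytest.approx(157.5)
        assert p.waits["treatment"] == pytest.approx(157.5 - 12.0)
        assert p.outcome == "treated"
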