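# Methods

## Model scope and assumptions

`rtsim` models one business day of a stand-alone radiotherapy centre as a
terminating discrete-event simulation: no warm-up, no carry-over between
days, each replication an independent day. Only processes requiring patient
presence are modelled (arrival, entrance screening, check-in, the six
treatment processes, exit); treatment planning and equipment QA happen in
staff time outside the patient-facing day and are out of scope, as are
multi-day fraction courses, no-shows and referral dynamics.

Core assumptions:

1. Single centre, no external dependencies.
2. Single-queue multi-server FIFO; patients are never assigned to a specific
   staff member or machine. A request that cannot currently be satisfied is
   skipped in the queue scan, so FIFO holds among satisfiable requests and a
   blocked team request cannot deadlock the centre.
3. All patients exist at day start and arrive per their stream's
   interarrival draw.
4. Unseen patients are those who (i) arrive after closing (minute 600),
   (ii) need a resource with zero capacity on the day's roster (sent home at
   the door), or (iii) are still inside when the grace period ends
   (minute 630).
5. The medical physicist attends first fractions only; with ~2.5 first
   fractions/day the double-booking conflict is rare and bounded, so the
   0.1-FTE role is modelled as a capacity-1 pool available all day rather
   than as a 63-minute window (which would make first fractions nearly
   unschedulable and contradicts the observed pathway volumes).
6. Entrance measures: mask (1 min) + temperature (1 min) for everyone except
   known-COVID patients; a 15-min rapid test for patients with fever, the
   administrator staying with the patient throughout. The fever rule
   triggers exactly for new-COVID patients by default; a configurable fever
   probability for non-COVID patients exists (default 0, i.e. no false
   positives).
7. COVID-positive treatments block their resources 30 min longer (PPE,
   disinfection, ventilation). For known-COVID patients that time is
   pre-planned: every later arrival of the same stream shifts +30 min. For
   new-COVID patients it is an unplanned disruption.
8. Treatments are never interrupted — not by a staff availability boundary
   and not by the closing bell — but the minute-630 accounting cut is hard:
   a patient mid-treatment at 630 counts as unseen.

## Parameters, units, defaults

All times in minutes from 08:00; distances in metres; speeds in m/min.

| Parameter | Default | Why |
|---|---|---|
| Day horizon / closing | 630 / 600 | 10-h opening plus 30-min grace |
| Follow-up streams | 2 × 60 patients, U(8, 12) gaps | "10±2 min" per LINAC stream |
| Planning CT stream | 10 patients, U(25, 35) gaps | "30±5 min" |
| Oncologist stream | 16 patients, U(30, 45) gaps | spreads 16 slots over the day |
| Appointment mix | (9, 2.5, 2.4, 2.1)/16 | consultation, first fraction, final exam, aftercare |
| Follow-up fraction | triangular(3, 7, 10) | range 3–10, mode 7 |
| Planning CT | U(10, 20) | stated range |
| Consultation | U(20, 60) | stated range |
| First fraction | triangular(10, 15, 20) | mean 15 as stated |
| Final exam / aftercare | U(10, 20) | no separate data; same order as CT |
| Check-in | U(4, 6) new consultations, U(1, 3) otherwise | admission work is longer for new patients |
| Screening | 1 + 1 min, rapid test 15 min | stated durations |
| COVID extension | 30 min (treatment), 30 min (known-COVID slot shift) | stated |
| Roster | 2 oncologists @75%, 6 RTTs, 2 admins, 1 physicist, 2 LINACs, 1 CT | 1.5 / 6 / 2 / 0.1 FTE establishment |
| COVID rates | low: 19 572 new / 150 200 active; high: 296 498 / 4 246 200; population 83 166 711 | reporting-institute case counts at the two reference dates; the population is the official reference population used for incidence statistics, and reproduces the four published per-patient rates at printed precision |
| Age | bands 40–90, peak 60–75 | coarse adult cancer-age shape (placeholder; sources give no printed table) |
| Walking speed | 70 / 60 / 48 m/min for <65 / 65–75 / ≥75 | age-banded gait speed |
| Distances | reception 15 m from entrance; LINAC 70 m, CT 50 m, consultation room 25 m from the waiting room; exits 80/60/35 m | floor-plan scale (LINAC bunkers at the corridor end) |

Interarrival "a±b" notation is read as U(a−b, a+b); distribution families
for service times are the simplest ones consistent with the stated supports
and modes, and every one of them is overridable in the YAML config. The
check-in durations, age table and distances are declared calibration
parameters: they come from practitioner elicitation ranges rather than a
printed table, and emergent congestion outcomes (severe-shortfall PACR,
maximum waits) are sensitive to them at the few-percentage-point level.

### Staff availability

An availability fraction f becomes a deterministic off-block of
(1−f)·630 min: even-indexed units are off at the start of the day,
odd-indexed at the end, so two 75% oncologists always leave one on duty.
Deterministic staggering (rather than random shifts) keeps runs reproducible
and matches the FTE-as-availability reading of the establishment numbers.

### Travel and resource holds

The walk from the waiting room to the treatment room happens *after* the
team is seized: staff receive the patient in the room, so the one-way walk
(~1 min at banded gait speeds) is part of the resource hold. The walk out
happens after release. Walks accrue to moving time; queueing intervals to
waiting time; service (plus COVID extension), screening and check-in to
process time. The three waiting buckets (screening queue, check-in queue,
pre-treatment) sum exactly to the reported cumulative wait.

## Synthetic population: what it emulates, what it does not

The generator reproduces the *operational* features of a centre's day:
fixed appointment books (120 + 10 + 16 patients), short-gap follow-up
streams, the appointment-type mix, per-patient COVID status at national
incidence/prevalence levels, and the known-COVID schedule stretch. It does
not emulate real patient heterogeneity — case-mix severity, mobility aids,
no-shows, arrival unpunctuality — nor intra-day demand waves. Passing tests
therefore show that the queueing mechanics and the relative scenario
rankings are right under the stated booking pattern, not that absolute
waits would match any particular real centre.

## Numerical and design choices

* Event ties break by insertion order; per-replication RNG streams derive
  from `SeedSequence(master, spawn_key=(scenario_id, replication))`; a run
  is bitwise reproducible from its manifest.
* All stochastic attributes of a day (arrivals, statuses, service and
  check-in draws) are drawn at generation time, so two scenarios compared
  under common random numbers share the identical patient day exactly; the
  process model itself is deterministic.
* Waiting-time denominators include every patient who entered the centre,
  also those still inside at the cut (their pending queue time accrues to
  minute 630); patients turned away at the door contribute to PACR but not
  to waiting times, since all modelled waiting causes occur inside.
* The per-replication maximum wait is summarised over replications
  (mean/max across 300 days), matching the "maximum waiting time" reading
  of the scenario narratives.
* Aggregation uses Student-t 95% intervals with the replication as the unit
  of analysis; 300 replications put the Monte-Carlo SE of PACR below half a
  percentage point in every scenario.
* Utilisation is busy time (clipped at minute 630) over scheduled
  availability; overtime created by the never-interrupt rule is clipped so
  utilisation stays in [0, 1].
* Zero-capacity demands fail fast at arrival ("sent home"); a first
  fraction with no oncologist configured is cancelled at the door.
* The preferential first-fraction rule reorders queues only; it never
  preempts an active grant.

## Problem sizes

The packaged experiments run each scenario for 300 one-day replications
(~146 patients, a few thousand events per day); the full 21-scenario sweep
completes in a few minutes on one CPU, and the bundled acceptance run
(4 scenarios × 300 days) in under a minute.

## Known limitations

* Congested-scenario outcomes depend on elicitation-range calibration
  parameters (check-in, distances); treat absolute severe-shortfall numbers
  as ±-a-few-points.
* The physicist simplification (assumption 5) slightly understates first-
  fraction conflicts on days with clustered first fractions.
* FTE-as-deterministic-window ignores breaks and stochastic absence within
  a day.
* Single-day termination cannot show backlog propagation across days — the
  clinically critical consequence of missed follow-up fractions is outside
  the model.
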