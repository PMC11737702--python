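# rtsim — radiotherapy centre operations under pandemic disruption

`rtsim` is a discrete-event simulation (DES) of a stand-alone radiotherapy
centre: two linear accelerators (LINACs), one planning CT, 1.5 FTE radiation
oncologists, six radiotherapy technologists (RTTs), two administrators and a
0.1-FTE medical physicist serving ~146 patients per ten-hour day. It
quantifies how COVID-19 protection measures at the entrance (masks,
temperature checks, rapid tests) and pandemic-related staff or equipment
absence change patient waiting times and daily throughput.

It is written for healthcare operations researchers and radiotherapy centre
planners who want a reproducible, scriptable what-if tool rather than a GUI
simulation product.

## Model in brief

Patients are generated at day start with a pathway (consultation, planning
CT, first fraction, follow-up fraction, final examination, aftercare), an
arrival time from their stream's interarrival distribution (follow-up
10±2 min per LINAC stream, CT 30±5 min, 16 oncologist appointments/day), an
age-banded walking speed, and a COVID-19 status drawn per patient:

```
P(new-COVID)   = incidence  = new cases / population
P(known-COVID) = prevalence = (active − new cases) / population
```

The centre is a single-queue, multi-server FIFO system; treatments seize
their whole resource team atomically (e.g. a first fraction needs
1 LINAC + 2 RTTs + 1 oncologist + 1 physicist) and a first-fraction team
request is allocated preferentially once the oncologist is secured. Each
COVID-positive treatment blocks its resources 30 min longer; known-COVID
patients are pre-planned (they shift later appointments of their stream by
+30 min and bypass entrance screening), new-COVID patients are unplanned
disruptions. The day closes at minute 600 with a 30-minute grace period;
whoever has not left by minute 630 counts as unseen.

The headline KPI is the patient appointment completion rate
PACR = treated / generated, reported with mean cumulative waiting times,
utilisation per resource pool, and Student-t 95% confidence intervals over
300 one-day replications. The experimental grid crosses seven rosters (full,
−1 oncologist, −2 RTT, −4 RTT, −1 administrator, combined, −1 LINAC) with
three COVID categories (none / low / high) into scenarios 0–20.

## Worked example

```python
from rtsim import build_scenario
from rtsim.cli import run_scenario

for sid in (0, 17):
    reps, summary = run_scenario(sid, n_reps=300, master_seed=42)
    ...
```

prints

```
scenario 0 (cat 1, none)
  overall PACR   : 98.5%  (95% CI 98.4-98.6)
  follow-up PACR : 99.0%  (95% CI 98.9-99.0)
  mean wait      : 0.9 min   max wait: 58 min
  LINAC utilisation: 77%   RTT utilisation: 60%
scenario 17 (cat 3, 4 RTT)
  overall PACR   : 47.0%  (95% CI 46.5-47.4)
  follow-up PACR : 38.4%  (95% CI 37.9-38.8)
  mean wait      : 162.9 min   max wait: 411 min
  LINAC utilisation: 38%   RTT utilisation: 98%
```

Scenario 0 is the undisturbed base case: slightly more patients are booked
than the closing rule admits, so the completion rate sits just under 100%
and waits are minutes. Scenario 17 (only 2 of 6 RTTs on duty, high COVID
rates with entrance screening) collapses throughput to below half: the RTT
pair becomes the bottleneck (98% utilisation), follow-up irradiation — the
pathway cancer patients must not interrupt — is hit hardest, and individual
patients queue for close to seven hours.

From the shell the same sweep is:

```bash
rtsim run --scenario all --reps 300 --seed 42 --out results/
rtsim report results/summary.csv --kpi pacr
```

which writes per-replication KPIs (`replications.csv`), scenario summaries
with confidence intervals (`summary.csv`) and a manifest echoing every
parameter and seed, so a run is reproducible byte-for-byte. YAML overrides
for rosters, service-time distributions, COVID rates and the travel table
are documented in `docs/methods.md` and checked by `rtsim validate`.

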