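"""Key performance indicators per replication and over replications.

A replication is one simulated day (:class:`DayResult`).  The headline KPI is
the patient appointment completion rate (PACR), the number of treated
patients divided by the number of generated patients, overall or restricted
to a pathway.  Waiting times are the per-patient cumulative queueing times
(entrance protection queue + check-in queue + pre-treatment wait) over all
admitted patients, i.e. patients who entered the centre, whether or not they
finished before the grace-period cut.  Replications are aggregated with
Student-t 95% confidence intervals; the replication is the unit of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import PATHWAYS, Patient

POOL_NAMES = ("oncologist", "rtt", "administrator", "physicist", "linac", "ct")


@dataclass
class DayResult:
    """Everything recorded about one replication."""

    patients: List[Patient]
    pool_busy: Dict[str, float]
    pool_available: Dict[str, float]
    grant_log: List[dict] = field(default_factory=list)

    @property
    def n_generated(self) -> int:
        return len(self.patients)

    @property
    def n_treated(self) -> int:
        return sum(1 for p in self.patients if p.outcome == "treated")

    @property
    def n_unseen(self) -> int:
        return sum(1 for p in self.patients if p.outcome == "unseen")

    def admitted(self) -> List[Patient]:
        return [p for p in self.patients if p.admitted]

    def to_frame(self) -> pd.DataFrame:
        from .population import population_frame

        return population_frame(self.patients)


def compute_pacr(day: DayResult, pathway: Optional[str] = None) -> Optional[float]:
    """Treated / generated, optionally restricted to one pathway.

    Returns ``None`` (reported as missing) when no patient of the requested
    pathway was generated.
    """
    pats = day.patients
    if pathway is not None:
        pats = [p for p in pats if p.pathway == pathway]
    if not pats:
        return None
    treated = sum(1 for p in pats if p.outcome == "treated")
    return treated / len(pats)


def waiting_summary(day: DayResult) -> pd.DataFrame:
    """Mean and max cumulative waiting time (minutes), overall and per pathway.

    The denominator is the admitted patients: the queueing causes all occur
    inside the centre, so patients turned away at the door (after-hours or
    zero-capacity arrivals) do not contribute.
    """
    admitted = day.admitted()
    rows = {}
    groups = [("overall", admitted)] + [
        (pw, [p for p in admitted if p.pathway == pw]) for pw in PATHWAYS
    ]
    for label, group in groups:
        if not group:
            rows[label] = {"n": 0, "mean_wait": np.nan, "max_wait": np.nan}
            continue
        waits = [p.total_wait for p in group]
        rows[label] = {
            "n": len(group),
            "mean_wait": float(np.mean(waits)),
            "max_wait": float(np.max(waits)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def utilisation(day: DayResult, pool: str) -> Optional[float]:
    """Busy time / scheduled-available time; ``None`` if never available."""
    available = day.pool_available.get(pool, 0.0)
    if available <= 0:
        return None
    return min(day.pool_busy.get(pool, 0.0) / available, 1.0)


def kpi_row(day: DayResult) -> Dict[str, float]:
    """Flatten one replication into the per-replication KPI table row."""
    row: Dict[str, float] = {
        "generated": day.n_generated,
        "treated": day.n_treated,
        "unseen": day.n_unseen,
        "pacr": compute_pacr(day),
    }
    for pw in PATHWAYS:
        pats = [p for p in day.patients if p.pathway == pw]
        row[f"generated_{pw}"] = len(pats)
        row[f"treated_{pw}"] = sum(1 for p in pats if p.outcome == "treated")
        pacr = compute_pacr(day, pw)
        row[f"pacr_{pw}"] = np.nan if pacr is None else pacr
    wsum = waiting_summary(day)
    row["mean_wait"] = wsum.loc["overall", "mean_wait"]
    row["max_wait"] = wsum.loc["overall", "max_wait"]
    for pw in PATHWAYS:
        row[f"mean_wait_{pw}"] = wsum.loc[pw, "mean_wait"]
    admitted = day.admitted()
    row["mean_process_time"] = (
        float(np.mean([p.process_time for p in admitted])) if admitted else np.nan
    )
    row["mean_moving_time"] = (
        float(np.mean([p.moving_time for p in admitted])) if admitted else np.nan
    )
    for pool in POOL_NAMES:
        util = utilisation(day, pool)
        row[f"util_{pool}"] = np.nan if util is None else util
    return row


@dataclass
class ScenarioSummary:
    """Replication-aggregated KPI means with 95% confidence intervals."""

    n_reps: int
    table: pd.DataFrame  # index: kpi, columns: mean, sd, ci_low, ci_high

    def __getitem__(self, kpi: str) -> float:
        return float(self.table.loc[kpi, "mean"])

    def ci(self, kpi: str):
        return (
            float(self.table.loc[kpi, "ci_low"]),
            float(self.table.loc[kpi, "ci_high"]),
        )


def aggregate(replications: Sequence, confidence: float = 0.95) -> ScenarioSummary:
    """Aggregate per-replication KPIs into means, sds and t-based CIs.

    ``replications`` may be :class:`DayResult` objects or pre-computed KPI
    row dicts.  Requires at least two replications for the CI to exist.
    """
    reps = list(replications)
    if len(reps) < 2:
        raise ValueError("need at least 2 replications to aggregate")
    rows = [kpi_row(r) if isinstance(r, DayResult) else dict(r) for r in reps]
    frame = pd.DataFrame(rows)
    n = len(frame)
    tq = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    mean = frame.mean()
    sd = frame.std(ddof=1)
    half = tq * sd / np.sqrt(n)
    table = pd.DataFrame(
        {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half}
    )
    return ScenarioSummary(n_reps=n, table=table)
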