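"""Minimal process-oriented discrete-event kernel.

The kernel provides three things and nothing more:

* a simulation clock with a future-event list (:class:`Engine`),
* generator-based processes driven by yielded effects (:class:`Delay`,
  :class:`Seize`), and
* FIFO multi-server resource pools with scheduled per-unit availability
  windows and atomic multi-pool seizing (:class:`ResourceManager`).

Time is measured in minutes from the opening of the day.  Events scheduled
beyond the engine horizon never execute: the day simply ends first.

Queueing discipline
-------------------
All pending seize requests live in a single ordered list.  Whenever resource
state changes, the list is scanned in order and every request whose *full*
demand set is satisfiable is granted (all-or-nothing).  A request that cannot
currently be satisfied is skipped, so FIFO order holds among satisfiable
requests but a small later request may overtake a large blocked one.  Priority
requests are inserted at the head of the list (after earlier priority
requests).  Ties on the event heap are broken by insertion order, which makes
a run fully deterministic given its inputs.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Generator, List, Optional, Tuple

Windows = List[Tuple[float, float]]


class SchedulingError(RuntimeError):
    """An event was scheduled in the past: a logic bug in the caller."""


class ReleaseError(RuntimeError):
    """A grant was released twice."""


class UnservableRequestError(ValueError):
    """A demand exceeds the configured capacity of a pool and can never be
    satisfied.  Used by the centre's sent-home rule."""


class Engine:
    """Simulation clock plus future-event list.

    Parameters
    ----------
    horizon:
        Last instant at which events may execute, in minutes.  The default of
        630 is a ten-hour day plus a 30-minute grace period.
    """

    def __init__(self, horizon: float = 630.0) -> None:
        self.now: float = 0.0
        self.horizon = float(horizon)
        self._heap: list = []
        self._counter = itertools.count()

    def schedule(self, time: float, action: Callable[[], None]):
        """Schedule ``action`` at ``time``; ties run in insertion order."""
        if time < self.now - 1e-9:
            raise SchedulingError(
                f"event scheduled at t={time} before current time t={self.now}"
            )
        entry = (float(time), next(self._counter), action)
        heapq.heappush(self._heap, entry)
        return entry

    def run(self) -> None:
        """Process events in (time, insertion) order up to the horizon."""
        while self._heap:
            time, _, action = heapq.heappop(self._heap)
            if time > self.horizon:
                break  # day over; later events are discarded unexecuted
            self.now = time
            action()

    # -- generator-based processes ------------------------------------

    def launch(self, process: Generator) -> None:
        """Start a process generator; it yields Delay/Seize effects."""
        self._advance(process, None)

    def _advance(self, process: Generator, value) -> None:
        try:
            effect = process.send(value)
        except StopIteration:
            return
        effect._bind(self, process)


class Delay:
    """Effect: suspend the yielding process for ``duration`` minutes."""

    __slots__ = ("duration",)

    def __init__(self, duration: float) -> None:
        if duration < 0:
            raise ValueError(f"negative delay {duration}")
        self.duration = float(duration)

    def _bind(self, engine: Engine, process: Generator) -> None:
        engine.schedule(
            engine.now + self.duration, lambda: engine._advance(process, None)
        )


class Seize:
    """Effect: atomically request units from one or more pools.

    The process resumes with the :class:`Grant` once every demanded unit can
    be assigned simultaneously.  ``tag`` labels the queue for waiting-time
    decomposition (e.g. ``"screening"``, ``"checkin"``, ``"treatment"``).
    """

    __slots__ = ("manager", "demands", "priority", "tag", "owner")

    def __init__(
        self,
        manager: "ResourceManager",
        demands: Dict[str, int],
        *,
        priority: bool = False,
        tag: str = "",
        owner: Optional[int] = None,
    ) -> None:
        self.manager = manager
        self.demands = dict(demands)
        self.priority = priority
        self.tag = tag
        self.owner = owner

    def _bind(self, engine: Engine, process: Generator) -> None:
        self.manager.request(
            self.demands,
            priority=self.priority,
            tag=self.tag,
            owner=self.owner,
            on_grant=lambda grant: engine._advance(process, grant),
        )


@dataclass
class Unit:
    """One interchangeable server within a pool.

    Identity is kept only for availability windows and utilisation
    accounting; requests are never addressed to a specific unit.
    """

    index: int
    windows: Windows
    busy: bool = False
    busy_since: float = math.nan
    busy_time: float = 0.0

    def on_duty(self, t: float) -> bool:
        return any(start <= t < end for start, end in self.windows)

    def scheduled_minutes(self) -> float:
        return sum(end - start for start, end in self.windows)


class Pool:
    """A named staff or equipment group with FIFO-shared units."""

    def __init__(self, name: str, units: List[Unit]) -> None:
        self.name = name
        self.units = units

    @property
    def capacity(self) -> int:
        return len(self.units)

    def free_on_duty(self, t: float) -> List[Unit]:
        return [u for u in self.units if not u.busy and u.on_duty(t)]

    def busy_count(self) -> int:
        return sum(1 for u in self.units if u.busy)

    def scheduled_minutes(self) -> float:
        return sum(u.scheduled_minutes() for u in self.units)

    def busy_minutes(self, upto: float) -> float:
        """Accumulated busy time, counting in-progress holds up to ``upto``."""
        total = sum(u.busy_time for u in self.units)
        for u in self.units:
            if u.busy:
                total += max(0.0, min(upto, math.inf) - u.busy_since)
        return total


@dataclass
class SeizeRequest:
    seq: int
    demands: Dict[str, int]
    request_time: float
    priority: bool
    tag: str
    owner: Optional[int]
    on_grant: Callable[["Grant"], None] = field(repr=False, default=None)


@dataclass
class Grant:
    """An active hold on a set of units; release them together, exactly once."""

    request: SeizeRequest
    units: Dict[str, List[Unit]]
    time: float
    _manager: "ResourceManager" = field(repr=False, default=None)
    active: bool = True

    @property
    def wait(self) -> float:
        """Queueing time accrued between request and grant."""
        return self.time - self.request.request_time

    def release(self) -> None:
        if not self.active:
            raise ReleaseError(
                f"grant for request #{self.request.seq} released twice"
            )
        self.active = False
        now = self._manager.engine.now
        for units in self.units.values():
            for unit in units:
                unit.busy = False
                unit.busy_time += now - unit.busy_since
                unit.busy_since = math.nan
        self._manager._schedule_scan()


class ResourceManager:
    """Owns the pools, the shared request queue and the grant log."""

    def __init__(self, engine: Engine, pools: Dict[str, Pool]) -> None:
        self.engine = engine
        self.pools = pools
        self.pending: List[SeizeRequest] = []
        self.grant_log: List[dict] = []
        self._req_counter = itertools.count()
        # a unit coming on duty can unblock queued requests
        starts = {
            start
            for pool in pools.values()
            for unit in pool.units
            for start, _ in unit.windows
            if start > 0
        }
        for start in sorted(starts):
            engine.schedule(start, self._scan)

    def request(
        self,
        demands: Dict[str, int],
        *,
        priority: bool = False,
        tag: str = "",
        owner: Optional[int] = None,
        on_grant: Callable[[Grant], None],
    ) -> SeizeRequest:
        for name, n in demands.items():
            if n <= 0:
                raise ValueError(f"demand for {name!r} must be positive")
            pool = self.pools.get(name)
            if pool is None or pool.capacity < n:
                raise UnservableRequestError(
                    f"demand {name}:{n} exceeds configured capacity "
                    f"{0 if pool is None else pool.capacity}"
                )
        req = SeizeRequest(
            seq=next(self._req_counter),
            demands=dict(demands),
            request_time=self.engine.now,
            priority=priority,
            tag=tag,
            owner=owner,
            on_grant=on_grant,
        )
        if priority:
            pos = 0
            while pos < len(self.pending) and self.pending[pos].priority:
                pos += 1
            self.pending.insert(pos, req)
        else:
            self.pending.append(req)
        self._scan()
        return req

    def _schedule_scan(self) -> None:
        self.engine.schedule(self.engine.now, self._scan)

    def _scan(self) -> None:
        """Grant, in queue order, every request now fully satisfiable."""
        t = self.engine.now
        granted: List[Tuple[SeizeRequest, Grant]] = []
        remaining: List[SeizeRequest] = []
        for req in self.pending:
            assignment: Dict[str, List[Unit]] = {}
            ok = True
            for name, n in req.demands.items():
                free = self.pools[name].free_on_duty(t)
                if len(free) < n:
                    ok = False
                    break
                assignment[name] = free[:n]
            if not ok:
                remaining.append(req)
                continue
            for units in assignment.values():
                for unit in units:
                    unit.busy = True
                    unit.busy_since = t
            grant = Grant(request=req, units=assignment, time=t, _manager=self)
            self.grant_log.append(
                {
                    "request_seq": req.seq,
                    "request_time": req.request_time,
                    "grant_time": t,
                    "priority": req.priority,
                    "tag": req.tag,
                    "owner": req.owner,
                    "demands": dict(req.demands),
                }
            )
            granted.append((req, grant))
        self.pending = remaining
        # resume processes only after the scan so a resumed process cannot
        # disturb the in-order sweep above
        for req, grant in granted:
            req.on_grant(grant)

    # -- end-of-day accounting ----------------------------------------

    def finalize(self, upto: Optional[float] = None) -> None:
        """Close the books: clip in-progress holds at ``upto`` (default the
        engine horizon).  Pending requests stay queued for the caller to
        account as unserved."""
        cut = self.engine.horizon if upto is None else upto
        for pool in self.pools.values():
            for unit in pool.units:
                if unit.busy:
                    unit.busy_time += max(0.0, cut - unit.busy_since)
                    unit.busy = False
                    unit.busy_since = math.nan

    def busy_summary(self, upto: Optional[float] = None) -> Dict[str, float]:
        cut = self.engine.horizon if upto is None else upto
        return {
            name: min(pool.busy_minutes(cut), pool.scheduled_minutes())
            for name, pool in self.pools.items()
        }
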