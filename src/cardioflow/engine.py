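"""A minimal deterministic discrete-event kernel.

Three pieces: an event calendar ordered by ``(time, insertion sequence)``,
resource pools with priority queues and occupancy/blocking accounting, and
named seeded random substreams.  Continuous time, in hours, as floating
point; no discretisation.

The kernel is deliberately small: no preemption, no batching, no
hierarchical resources.  Determinism is a hard requirement — identical
seed and configuration must reproduce the identical event trace — so ties
in the calendar break by global insertion order and every stochastic
mechanism draws from its own named substream (which also enables
common-random-number comparisons across scenarios).
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass
from typing import Callable, Hashable

import numpy as np

__all__ = ["SchedulingError", "AccountingError", "Simulator", "ResourcePool", "RngStreams"]


class SchedulingError(RuntimeError):
    """Scheduling an event in the past."""


class AccountingError(RuntimeError):
    """Resource bookkeeping violation (e.g. release by a non-holder)."""


class Simulator:
    """Event calendar plus simulation clock."""

    def __init__(self) -> None:
        self.now: float = 0.0
        self._heap: list[tuple[float, int, Callable[[], None]]] = []
        self._seq: int = 0
        self.events_executed: int = 0

    def schedule(self, time: float, action: Callable[[], None]) -> tuple[float, int]:
        """Enqueue *action* at *time*; returns the (time, seq) handle."""
        if time < self.now:
            raise SchedulingError(f"cannot schedule at t={time} < now={self.now}")
        self._seq += 1
        handle = (time, self._seq)
        heapq.heappush(self._heap, (time, self._seq, action))
        return handle

    def schedule_in(self, delay: float, action: Callable[[], None]) -> tuple[float, int]:
        return self.schedule(self.now + delay, action)

    def run_until(self, horizon: float) -> None:
        """Execute events in (time, seq) order until the calendar is empty
        or the next event lies beyond *horizon*; the clock ends at *horizon*."""
        while self._heap and self._heap[0][0] <= horizon:
            time, _seq, action = heapq.heappop(self._heap)
            self.now = time
            self.events_executed += 1
            action()
        self.now = horizon


@dataclass
class _Waiter:
    priority: float
    seq: int
    entity: Hashable
    grant: Callable[[], None]
    enqueued_at: float


class ResourcePool:
    """Counted resource with a priority queue (lower priority value = served
    first; FIFO within a priority class) and time-weighted occupancy log."""

    def __init__(self, sim: Simulator, name: str, capacity: int) -> None:
        if capacity < 1:
            raise ValueError(f"pool {name!r}: capacity must be >= 1")
        self.sim = sim
        self.name = name
        self.capacity = capacity
        self.in_use = 0
        self._holders: set = set()
        self._queue: list[tuple[float, int, _Waiter]] = []
        self._qseq = 0
        self.blocked_time_total = 0.0  # hours of bed-blocking attributed to this pool
        self.grants = 0
        self.releases = 0
        # step history of (time, in_use), for utilisation integrals
        self._history: list[tuple[float, int]] = [(0.0, 0)]

    # -- internals -------------------------------------------------------
    def _log(self) -> None:
        self._history.append((self.sim.now, self.in_use))

    def _grant_to(self, waiter: _Waiter) -> None:
        self.in_use += 1
        self.grants += 1
        self._holders.add(waiter.entity)
        self._log()
        waiter.grant()

    # -- interface -------------------------------------------------------
    def acquire(self, entity: Hashable, grant: Callable[[], None], priority: float = 0.0) -> bool:
        """Request one unit for *entity*.  If a unit is free it is granted
        synchronously (*grant* is called before returning) and True is
        returned; otherwise the request queues and *grant* will run, as a
        scheduled event, when a unit is released to this entity."""
        if entity in self._holders:
            raise AccountingError(f"{entity!r} already holds a unit of {self.name!r}")
        if self.in_use < self.capacity:
            self._grant_to(_Waiter(priority, 0, entity, grant, self.sim.now))
            return True
        self._qseq += 1
        w = _Waiter(priority, self._qseq, entity, grant, self.sim.now)
        heapq.heappush(self._queue, (priority, self._qseq, w))
        return False

    def cancel_request(self, entity: Hashable) -> None:
        """Withdraw a queued (not yet granted) request."""
        self._queue = [(p, s, w) for (p, s, w) in self._queue if w.entity != entity]
        heapq.heapify(self._queue)

    def release(self, entity: Hashable) -> None:
        if entity not in self._holders:
            raise AccountingError(f"{entity!r} does not hold a unit of {self.name!r}")
        self._holders.remove(entity)
        self.in_use -= 1
        self.releases += 1
        self._log()
        if self._queue:
            _p, _s, waiter = heapq.heappop(self._queue)
            # grant as a same-time event so execution order stays (time, seq)
            self.sim.schedule(self.sim.now, lambda w=waiter: self._grant_to(w))

    def add_blocked_time(self, hours: float) -> None:
        if hours < 0:
            raise AccountingError("blocked time increments must be >= 0")
        self.blocked_time_total += hours

    @property
    def queue_length(self) -> int:
        return len(self._queue)

    # -- statistics ------------------------------------------------------
    def occupancy_integral(self, t0: float, t1: float) -> float:
        """∫ in_use dt over [t0, t1] (unit-hours), from the step history."""
        if t1 <= t0:
            return 0.0
        total = 0.0
        hist = self._history
        for i, (t, level) in enumerate(hist):
            t_next = hist[i + 1][0] if i + 1 < len(hist) else max(t1, self.sim.now)
            lo, hi = max(t, t0), min(t_next, t1)
            if hi > lo:
                total += level * (hi - lo)
        return total

    def mean_occupancy(self, t0: float, t1: float) -> float:
        return self.occupancy_integral(t0, t1) / (t1 - t0)

    def utilisation(self, t0: float, t1: float) -> float:
        return self.mean_occupancy(t0, t1) / self.capacity


class RngStreams:
    """Named, individually reproducible random substreams.

    Substreams are derived from the master seed and a stable 32-bit hash of
    the stream name, so adding a new mechanism never perturbs existing
    streams and scenario variants can share e.g. the arrival stream
    (common random numbers).
    """

    def __init__(self, master_seed: int) -> None:
        self.master_seed = int(master_seed)
        self._streams: dict[str, np.random.Generator] = {}

    @staticmethod
    def _key(name: str) -> int:
        return zlib.crc32(name.encode("utf-8"))

    def stream(self, name: str) -> np.random.Generator:
        if name not in self._streams:
            ss = np.random.SeedSequence([self.master_seed, self._key(name)])
            self._streams[name] = np.random.default_rng(ss)
        return self._streams[name]

    def fresh(self, name: str) -> np.random.Generator:
        """A new generator for *name*, independent of any cached one's state."""
        ss = np.random.SeedSequence([self.master_seed, self._key(name)])
        return np.random.default_rng(ss)
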