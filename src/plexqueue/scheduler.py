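"""ipTM priority propagation and dead-end elimination over the complex queue.

The queue is a containment lattice: every candidate complex of size k+1
contains candidate subcomplexes of size k. Scheduling proceeds strictly
level by level (all dimers before any trimer, etc.):

1. *Dimer evaluation.* Every dimer is computed. When a dimer's ipTM meets
   the user threshold, every larger pending complex containing that dimer
   receives a priority equal to the ipTM — or keeps its existing priority
   if that is already higher (priorities only ever increase).
2. *Dead-end elimination.* Once a level is fully resolved, every larger
   pending complex whose priority is still unset or below the threshold is
   marked ``poisoned`` and never computed. Because propagation uses the
   maximum over subcomplexes, a complex survives as long as *any* of its
   scored subcomplexes met the threshold — this is what keeps linear /
   bridged assemblies (where one pairwise interface is weak) alive.
3. *Prioritised higher orders.* Within a level, pending complexes are
   dispatched best-priority-first; each result propagates upward exactly as
   dimer results do.

No removal happens until the whole current level is resolved, and poisoning
is final: a later high score cannot resurrect a poisoned record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Protocol

from .backends import PredictionResult
from .enumeration import ComplexSpec
from .errors import SchedulerError

__all__ = [
    "Status",
    "QueueRecord",
    "SchedulerConfig",
    "RecordStore",
    "MemoryStore",
    "CampaignSummary",
    "propagate_priority",
    "poison_dead_ends",
    "next_job",
    "record_result",
    "record_failure",
    "run_campaign",
]

log = logging.getLogger(__name__)


class Status(str, Enum):
    PENDING = "pending"
    RUNNING = "running"
    DONE = "done"
    FAILED = "failed"
    POISONED = "poisoned"


@dataclass
class QueueRecord:
    """One queued candidate complex with its lifecycle state.

    Invariants: a poisoned record never holds a result, a done record
    always does, and priority only ever increases once set.
    """

    complex: ComplexSpec
    status: Status = Status.PENDING
    priority: Optional[float] = None
    result: Optional[PredictionResult] = None
    attempts: int = 0

    @property
    def canonical_name(self) -> str:
        return self.complex.canonical_name

    @property
    def size(self) -> int:
        return self.complex.size


@dataclass
class SchedulerConfig:
    """Campaign parameters.

    priority_threshold is the ipTM a subcomplex must reach for its score to
    propagate (default 0.5; useful values run up to ~0.8-0.9 for
    well-folded interactomes). max_attempts=1 means a failing job is
    abandoned after one try; failures never propagate or poison.
    """

    priority_threshold: float = 0.5
    max_level: int = 4
    max_attempts: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.priority_threshold <= 1.0):
            raise SchedulerError(
                f"priority_threshold must be in [0,1], got {self.priority_threshold}")
        if self.max_level < 2:
            raise SchedulerError("max_level must be >= 2")
        if self.max_attempts < 1:
            raise SchedulerError("max_attempts must be >= 1")


class RecordStore(Protocol):
    """Minimal store contract the scheduler operates against.

    Implemented by the in-memory store below and by the SQLite-backed
    ``JobStore``; both enforce the QueueRecord state-machine invariants.
    """

    def add(self, spec: ComplexSpec) -> QueueRecord: ...
    def get(self, name: str) -> QueueRecord: ...
    def records(self, status: Optional[Status] = None,
                size: Optional[int] = None) -> list[QueueRecord]: ...
    def set_priority(self, name: str, value: float) -> None: ...
    def transition(self, name: str, new: Status,
                   expect: Optional[Iterable[Status]] = None) -> QueueRecord: ...
    def store_result(self, name: str, result: PredictionResult) -> None: ...
    def bump_attempts(self, name: str) -> int: ...


class MemoryStore:
    """Dict-backed RecordStore for tests and single-process campaigns."""

    def __init__(self) -> None:
        self._records: dict[str, QueueRecord] = {}

    def add(self, spec: ComplexSpec) -> QueueRecord:
        name = spec.canonical_name
        if name in self._records:
            return self._records[name]
        rec = QueueRecord(complex=spec)
        self._records[name] = rec
        return rec

    def get(self, name: str) -> QueueRecord:
        try:
            return self._records[name]
        except KeyError:
            raise SchedulerError(f"complex {name!r} is not in the queue") from None

    def records(self, status: Optional[Status] = None,
                size: Optional[int] = None) -> list[QueueRecord]:
        out = [r for r in self._records.values()
               if (status is None or r.status == status)
               and (size is None or r.size == size)]
        return sorted(out, key=lambda r: (r.size, r.canonical_name))

    def set_priority(self, name: str, value: float) -> None:
        rec = self.get(name)
        if rec.priority is not None and value < rec.priority:
            raise SchedulerError(
                f"priority of {name} may only increase "
                f"({rec.priority} -> {value})")
        rec.priority = value

    def transition(self, name: str, new: Status,
                   expect: Optional[Iterable[Status]] = None) -> QueueRecord:
        rec = self.get(name)
        if expect is not None and rec.status not in tuple(expect):
            raise SchedulerError(
                f"{name}: cannot move {rec.status.value} -> {new.value} "
                f"(expected one of {[s.value for s in expect]})")
        rec.status = new
        return rec

    def store_result(self, name: str, result: PredictionResult) -> None:
        rec = self.get(name)
        if rec.status == Status.POISONED:
            raise SchedulerError(
                f"{name} is poisoned and cannot hold a result")
        rec.result = result

    def bump_attempts(self, name: str) -> int:
        rec = self.get(name)
        rec.attempts += 1
        return rec.attempts

    def __len__(self) -> int:
        return len(self._records)


def propagate_priority(store: RecordStore, scored: ComplexSpec, iptm: float,
                       config: SchedulerConfig) -> int:
    """Lift the priority of every pending supercomplex of a scored complex.

    Only scores at or above the priority threshold propagate; the update is
    monotone (max of old and new priority). Returns the number of records
    whose priority changed.
    """
    rec = store.get(scored.canonical_name)
    if rec.status != Status.DONE:
        raise SchedulerError(
            f"{scored.canonical_name} has status {rec.status.value}; only done "
            "complexes propagate priority")
    if iptm < config.priority_threshold:
        return 0
    updated = 0
    for target in store.records(status=Status.PENDING):
        if target.size <= scored.size:
            continue
        if not target.complex.contains(scored, strict=True):
            continue
        if target.priority is None or iptm > target.priority:
            store.set_priority(target.canonical_name, iptm)
            updated += 1
    return updated


def poison_dead_ends(store: RecordStore, completed_level: int,
                     config: SchedulerConfig) -> int:
    """Dead-end elimination at a level boundary.

    Precondition: every record at ``completed_level`` is resolved (done,
    failed or poisoned) — elimination never runs while pairwise (or
    current-level) evaluations are outstanding. Every pending record larger
    than the completed level whose priority never reached the threshold is
    poisoned. Poisoning is final.
    """
    unresolved = [r for r in store.records(size=completed_level)
                  if r.status in (Status.PENDING, Status.RUNNING)]
    if unresolved:
        names = [r.canonical_name for r in unresolved[:5]]
        raise SchedulerError(
            f"cannot poison after level {completed_level}: unresolved records "
            f"remain at that level (e.g. {names})")
    poisoned = 0
    for rec in store.records(status=Status.PENDING):
        if rec.size <= completed_level:
            continue
        if rec.priority is None or rec.priority < config.priority_threshold:
            store.transition(rec.canonical_name, Status.POISONED,
                             expect=(Status.PENDING,))
            poisoned += 1
    return poisoned


def _dispatch_key(rec: QueueRecord):
    # priority desc (unset sorts last), then canonical name asc
    pri = rec.priority if rec.priority is not None else float("-inf")
    return (-pri, rec.canonical_name)


def next_job(store: RecordStore, current_level: int,
             config: SchedulerConfig) -> Optional[QueueRecord]:
    """Highest-priority pending record at the current level, or None when
    the level is exhausted. Dimers carry no priority and dispatch in
    canonical-name order; ties at higher levels break the same way."""
    pending = store.records(status=Status.PENDING, size=current_level)
    if not pending:
        return None
    return min(pending, key=_dispatch_key)


def record_result(store: RecordStore, spec: ComplexSpec,
                  result: PredictionResult,
                  config: SchedulerConfig) -> QueueRecord:
    """Mark a running job done, store its scores and propagate its ipTM
    upward through the containment lattice."""
    rec = store.get(spec.canonical_name)
    if rec.status == Status.DONE:
        log.warning("duplicate result for %s ignored", spec.canonical_name)
        return rec
    store.transition(spec.canonical_name, Status.DONE, expect=(Status.RUNNING,))
    store.store_result(spec.canonical_name, result)
    propagate_priority(store, spec, result.iptm, config)
    return store.get(spec.canonical_name)


def record_failure(store: RecordStore, spec: ComplexSpec, reason: str,
                   config: SchedulerConfig) -> QueueRecord:
    """Record an attrition event (timeout, memory, engine error).

    The job returns to pending until max_attempts is exhausted, then fails
    permanently. Failed complexes never propagate scores; their
    supercomplexes are judged on the remaining evidence.
    """
    name = spec.canonical_name
    rec = store.get(name)
    if rec.status != Status.RUNNING:
        raise SchedulerError(
            f"failure reported for {name} with status {rec.status.value}")
    attempts = store.bump_attempts(name)
    final = attempts >= config.max_attempts
    store.transition(name, Status.FAILED if final else Status.PENDING,
                     expect=(Status.RUNNING,))
    log.warning("job %s failed (%s): attempt %d/%d%s", name, reason, attempts,
                config.max_attempts, "; abandoned" if final else "; requeued")
    return store.get(name)


@dataclass
class CampaignSummary:
    """Per-level outcome counts plus the exact dispatch trace."""

    levels: dict[int, dict[str, int]] = field(default_factory=dict)
    dispatch_trace: list[str] = field(default_factory=list)
    config: Optional[SchedulerConfig] = None

    def total(self, status: str) -> int:
        return sum(c.get(status, 0) for c in self.levels.values())

    def to_json(self) -> str:
        payload = {
            "priority_threshold": self.config.priority_threshold if self.config else None,
            "levels": {str(k): v for k, v in sorted(self.levels.items())},
            "dispatched": len(self.dispatch_trace),
        }
        return json.dumps(payload, indent=2)

    def to_rows(self) -> list[dict]:
        return [{"level": lvl, **counts} for lvl, counts in sorted(self.levels.items())]


def run_campaign(store: RecordStore, scorer,
                 config: SchedulerConfig) -> CampaignSummary:
    """Drive a populated queue to completion against a scorer.

    Levels run strictly in order 2..max_level; dead-end elimination fires
    at every level boundary. ``scorer`` is any callable mapping a
    ComplexSpec to a PredictionResult; exceptions it raises are routed to
    the failure path, not propagated.
    """
    summary = CampaignSummary(config=config)
    sizes = {r.size for r in store.records()}
    if not sizes:
        return summary
    for level in range(2, config.max_level + 1):
        while True:
            rec = next_job(store, level, config)
            if rec is None:
                break
            store.transition(rec.canonical_name, Status.RUNNING,
                             expect=(Status.PENDING,))
            summary.dispatch_trace.append(rec.canonical_name)
            try:
                result = scorer(rec.complex)
            except Exception as exc:
                record_failure(store, rec.complex, str(exc), config)
            else:
                record_result(store, rec.complex, result, config)
        poison_dead_ends(store, level, config)
        counts: dict[str, int] = {s.value: 0 for s in Status}
        for r in store.records(size=level):
            counts[r.status.value] += 1
        if any(counts.values()):
            summary.levels[level] = counts
    return summary
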