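"""Embedded single-file job store with concurrency-safe claiming.

A single SQLite file holds the proteins, edges, queue records, results and
an append-only event log. Workers claim jobs atomically (compare-and-set
on the status column inside one immediate transaction), take a lease with
a wall-time deadline per resource class, and either report a result or let
the lease expire, after which the job becomes reclaimable. Ten-ish
concurrent workers is the intended scale.

The store implements the scheduler's ``RecordStore`` contract, so the
level-by-level campaign logic runs unchanged against memory or disk.
"""

from __future__ import annotations

import json
import logging
import math
import sqlite3
import time
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .backends import PredictionResult
from .enumeration import ComplexSpec
from .errors import SchedulerError, SchemaVersionError
from .interactome import InteractionEdge, InteractionGraph, ProteinEntry
from .scheduler import QueueRecord, Status

__all__ = [
    "SCHEMA_VERSION",
    "JobStore",
    "WorkerLease",
    "init_store",
    "claim_next",
    "report_ranking",
    "export_network",
    "replay_events",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta(
    key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS proteins(
    uniprot_id TEXT PRIMARY KEY, gene_name TEXT, sequence TEXT);
CREATE TABLE IF NOT EXISTS edges(
    a TEXT NOT NULL, b TEXT NOT NULL, evidence_type TEXT,
    evidence_count INTEGER, PRIMARY KEY(a, b));
CREATE TABLE IF NOT EXISTS queue(
    canonical_name TEXT PRIMARY KEY,
    size INTEGER NOT NULL,
    members TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'pending',
    priority REAL,
    attempts INTEGER NOT NULL DEFAULT 0,
    claim_token TEXT,
    worker_id TEXT,
    lease_deadline REAL);
CREATE TABLE IF NOT EXISTS results(
    canonical_name TEXT PRIMARY KEY,
    iptm REAL NOT NULL, ptm REAL, mean_plddt REAL,
    model_ref TEXT, model_rank INTEGER);
CREATE TABLE IF NOT EXISTS events(
    event_id INTEGER PRIMARY KEY AUTOINCREMENT,
    ts REAL NOT NULL, canonical_name TEXT, event TEXT NOT NULL,
    payload TEXT);
CREATE INDEX IF NOT EXISTS idx_queue_status ON queue(status, size);
"""


@dataclass
class WorkerLease:
    """A claimed job: at most one live lease per queue record; a lease past
    its deadline is reclaimable by any other worker."""

    worker_id: str
    claimed: str
    token: str
    deadline: float


class JobStore:
    """SQLite-backed RecordStore plus persistence for the whole pipeline."""

    def __init__(self, db_path):
        self.db_path = str(db_path)
        self._conn = sqlite3.connect(self.db_path, timeout=30.0,
                                     isolation_level=None,
                                     check_same_thread=False)
        self._conn.row_factory = sqlite3.Row
        self._conn.execute("PRAGMA busy_timeout=30000")

    # -- schema ----------------------------------------------------------

    def init_schema(self) -> "JobStore":
        cur = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE name='meta'")
        exists = cur.fetchone() is not None
        if exists:
            row = self._conn.execute(
                "SELECT value FROM meta WHERE key='schema_version'").fetchone()
            if row is not None and int(row["value"]) > SCHEMA_VERSION:
                raise SchemaVersionError(row["value"], str(SCHEMA_VERSION))
        self._conn.executescript(_SCHEMA)
        self._conn.execute(
            "INSERT OR IGNORE INTO meta(key, value) VALUES('schema_version', ?)",
            (str(SCHEMA_VERSION),))
        return self

    def close(self) -> None:
        self._conn.close()

    def _event(self, name: Optional[str], event: str, **payload) -> None:
        self._conn.execute(
            "INSERT INTO events(ts, canonical_name, event, payload) "
            "VALUES(?,?,?,?)",
            (time.time(), name, event, json.dumps(payload, sort_keys=True)))

    def log_config(self, **params) -> None:
        """Record a run's parameters so reports are self-describing."""
        self._event(None, "config", **params)

    # -- graph persistence ----------------------------------------------

    def save_graph(self, graph: InteractionGraph) -> None:
        with self._conn:
            for acc, p in sorted(graph.proteins.items()):
                self._conn.execute(
                    "INSERT INTO proteins(uniprot_id, gene_name, sequence) "
                    "VALUES(?,?,?) ON CONFLICT(uniprot_id) DO UPDATE SET "
                    "gene_name=COALESCE(excluded.gene_name, gene_name), "
                    "sequence=COALESCE(excluded.sequence, sequence)",
                    (acc, p.gene_name, p.sequence))
            for e in graph.edges:
                self._conn.execute(
                    "INSERT OR REPLACE INTO edges VALUES(?,?,?,?)",
                    (e.a, e.b, e.evidence_type, e.evidence_count))

    def load_graph(self) -> InteractionGraph:
        g = InteractionGraph()
        for row in self._conn.execute(
                "SELECT * FROM proteins ORDER BY uniprot_id"):
            g.add_protein(ProteinEntry(row["uniprot_id"], row["gene_name"],
                                       row["sequence"]))
        for row in self._conn.execute("SELECT * FROM edges ORDER BY a, b"):
            g.add_edge(InteractionEdge(row["a"], row["b"],
                                       row["evidence_type"] or "other-physical",
                                       row["evidence_count"] or 1))
        return g

    def sequences(self) -> dict[str, str]:
        return {row["uniprot_id"]: row["sequence"]
                for row in self._conn.execute(
                    "SELECT uniprot_id, sequence FROM proteins "
                    "WHERE sequence IS NOT NULL")}

    def set_sequence(self, accession: str, sequence: str) -> None:
        self._conn.execute(
            "INSERT INTO proteins(uniprot_id, sequence) VALUES(?,?) "
            "ON CONFLICT(uniprot_id) DO UPDATE SET sequence=excluded.sequence",
            (accession, sequence))

    # -- RecordStore contract -------------------------------------------

    def add(self, spec: ComplexSpec) -> QueueRecord:
        name = spec.canonical_name
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO queue(canonical_name, size, members, status)"
            " VALUES(?,?,?,'pending')",
            (name, spec.size, json.dumps(list(spec.members))))
        if cur.rowcount:
            self._event(name, "added", size=spec.size)
        return self.get(name)

    def _row_to_record(self, row) -> QueueRecord:
        spec = ComplexSpec.from_iterable(json.loads(row["members"]))
        result = None
        res = self._conn.execute(
            "SELECT * FROM results WHERE canonical_name=?",
            (row["canonical_name"],)).fetchone()
        if res is not None:
            result = PredictionResult(
                complex=spec, iptm=res["iptm"], ptm=res["ptm"] or 0.0,
                mean_plddt=res["mean_plddt"], model_ref=res["model_ref"],
                model_rank=res["model_rank"] or 1)
        return QueueRecord(complex=spec, status=Status(row["status"]),
                           priority=row["priority"], result=result,
                           attempts=row["attempts"])

    def get(self, name: str) -> QueueRecord:
        row = self._conn.execute(
            "SELECT * FROM queue WHERE canonical_name=?", (name,)).fetchone()
        if row is None:
            raise SchedulerError(f"complex {name!r} is not in the queue")
        return self._row_to_record(row)

    def records(self, status: Optional[Status] = None,
                size: Optional[int] = None) -> list[QueueRecord]:
        q = "SELECT * FROM queue WHERE 1=1"
        args: list = []
        if status is not None:
            q += " AND status=?"
            args.append(status.value)
        if size is not None:
            q += " AND size=?"
            args.append(size)
        q += " ORDER BY size, canonical_name"
        return [self._row_to_record(r) for r in self._conn.execute(q, args)]

    def set_priority(self, name: str, value: float) -> None:
        rec = self.get(name)
        if rec.priority is not None and value < rec.priority:
            raise SchedulerError(
                f"priority of {name} may only increase ({rec.priority} -> {value})")
        self._conn.execute(
            "UPDATE queue SET priority=? WHERE canonical_name=?", (value, name))
        self._event(name, "priority", value=value)

    def transition(self, name: str, new: Status,
                   expect: Optional[Iterable[Status]] = None) -> QueueRecord:
        rec = self.get(name)
        if expect is not None and rec.status not in tuple(expect):
            raise SchedulerError(
                f"{name}: cannot move {rec.status.value} -> {new.value} "
                f"(expected one of {[s.value for s in expect]})")
        self._conn.execute(
            "UPDATE queue SET status=?, claim_token=NULL, lease_deadline=NULL "
            "WHERE canonical_name=?", (new.value, name))
        self._event(name, "status", to=new.value)
        return self.get(name)

    def store_result(self, name: str, result: PredictionResult) -> None:
        rec = self.get(name)
        if rec.status == Status.POISONED:
            raise SchedulerError(f"{name} is poisoned and cannot hold a result")
        self._conn.execute(
            "INSERT OR REPLACE INTO results VALUES(?,?,?,?,?,?)",
            (name, result.iptm, result.ptm, result.mean_plddt,
             result.model_ref, result.model_rank))
        self._event(name, "result", iptm=result.iptm)

    def bump_attempts(self, name: str) -> int:
        self._conn.execute(
            "UPDATE queue SET attempts=attempts+1 WHERE canonical_name=?",
            (name,))
        n = self.get(name).attempts
        self._event(name, "attempt", n=n)
        return n

    def __len__(self) -> int:
        return self._conn.execute("SELECT COUNT(*) c FROM queue").fetchone()["c"]

    # -- claiming --------------------------------------------------------

    def claim_next(self, worker_id: str, level: int, wall_limit: float,
                   now: Optional[float] = None) -> Optional[WorkerLease]:
        """Atomically claim the job next_job would dispatch at this level.

        Expired leases are reset to pending (attempt counted) before
        selection. The claim itself is a compare-and-set on status inside
        an immediate transaction, so two concurrent claimers can never
        obtain the same record.
        """
        now = time.time() if now is None else now
        while True:
            try:
                self._conn.execute("BEGIN IMMEDIATE")
            except sqlite3.OperationalError:
                time.sleep(0.005)
                continue
            try:
                expired = self._conn.execute(
                    "SELECT canonical_name FROM queue WHERE status='running' "
                    "AND lease_deadline IS NOT NULL AND lease_deadline < ?",
                    (now,)).fetchall()
                for row in expired:
                    self._conn.execute(
                        "UPDATE queue SET status='pending', attempts=attempts+1,"
                        " claim_token=NULL, lease_deadline=NULL "
                        "WHERE canonical_name=?", (row["canonical_name"],))
                    self._event(row["canonical_name"], "lease_expired")
                row = self._conn.execute(
                    "SELECT canonical_name FROM queue WHERE status='pending' "
                    "AND size=? ORDER BY (priority IS NULL), priority DESC, "
                    "canonical_name LIMIT 1", (level,)).fetchone()
                if row is None:
                    self._conn.execute("COMMIT")
                    return None
                token = uuid.uuid4().hex
                deadline = now + wall_limit
                cur = self._conn.execute(
                    "UPDATE queue SET status='running', claim_token=?, "
                    "worker_id=?, lease_deadline=? WHERE canonical_name=? "
                    "AND status='pending'",
                    (token, worker_id, deadline, row["canonical_name"]))
                if cur.rowcount != 1:  # lost a race; retry selection
                    self._conn.execute("ROLLBACK")
                    continue
                self._event(row["canonical_name"], "claimed",
                            worker=worker_id, deadline=deadline)
                self._conn.execute("COMMIT")
                return WorkerLease(worker_id=worker_id,
                                   claimed=row["canonical_name"],
                                   token=token, deadline=deadline)
            except Exception:
                try:
                    self._conn.execute("ROLLBACK")
                except sqlite3.OperationalError:
                    pass
                raise

    # -- reporting -------------------------------------------------------

    def report_ranking(self, level: Optional[int] = None,
                       top_fraction: float = 1.0) -> pd.DataFrame:
        """Done complexes ranked by ipTM (descending, name as tie-break),
        cut to the top ceil(top_fraction * count) rows."""
        q = ("SELECT q.canonical_name, q.size, r.iptm, r.ptm, r.mean_plddt, "
             "q.status FROM queue q JOIN results r USING(canonical_name) "
             "WHERE q.status='done'")
        args: list = []
        if level is not None:
            q += " AND q.size=?"
            args.append(level)
        df = pd.read_sql_query(q, self._conn, params=args)
        if df.empty:
            log.warning("ranking requested but no complexes are done yet")
            return df
        df = df.sort_values(["iptm", "canonical_name"],
                            ascending=[False, True]).reset_index(drop=True)
        k = math.ceil(top_fraction * len(df))
        return df.head(k)

    def export_network(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node/edge tables for network visualisation.

        Nodes: one row per queue record (size class, status, poisoned flag,
        ipTM where available) plus one row per member protein. Edges link
        each complex to its member proteins. Deterministic ordering.
        """
        recs = self.records()
        node_rows = []
        edge_rows = []
        protein_ids = set()
        for r in recs:
            node_rows.append({
                "id": r.canonical_name,
                "kind": {2: "dimer", 3: "trimer", 4: "tetramer"}.get(
                    r.size, f"{r.size}-mer"),
                "size": r.size,
                "status": r.status.value,
                "poisoned": r.status == Status.POISONED,
                "iptm": r.result.iptm if r.result is not None else np.nan,
            })
            for member in sorted(set(r.complex.members)):
                protein_ids.add(member)
                edge_rows.append({"complex": r.canonical_name,
                                  "protein": member})
        for acc in sorted(protein_ids):
            node_rows.append({"id": acc, "kind": "protein", "size": 1,
                              "status": "", "poisoned": False, "iptm": np.nan})
        nodes = pd.DataFrame(node_rows).sort_values(
            ["size", "id"]).reset_index(drop=True)
        edges = pd.DataFrame(edge_rows).sort_values(
            ["complex", "protein"]).reset_index(drop=True)
        return nodes, edges


def init_store(db_path) -> JobStore:
    """Create (idempotently) and open the single-file job store."""
    Path(db_path).parent.mkdir(parents=True, exist_ok=True)
    return JobStore(db_path).init_schema()


def claim_next(store: JobStore, worker_id: str, level: int,
               wall_limit: float, now: Optional[float] = None
               ) -> Optional[WorkerLease]:
    return store.claim_next(worker_id, level, wall_limit, now=now)


def report_ranking(store: JobStore, level: Optional[int] = None,
                   top_fraction: float = 1.0) -> pd.DataFrame:
    return store.report_ranking(level=level, top_fraction=top_fraction)


def export_network(store: JobStore) -> tuple[pd.DataFrame, pd.DataFrame]:
    return store.export_network()


def replay_events(store: JobStore) -> dict[str, dict]:
    """Fold the event log into a {canonical_name: {status, priority,
    attempts}} snapshot; used to audit that the log replays to the live
    queue state."""
    state: dict[str, dict] = {}
    for row in store._conn.execute(
            "SELECT * FROM events ORDER BY event_id"):
        name = row["canonical_name"]
        if name is None:
            continue
        payload = json.loads(row["payload"] or "{}")
        s = state.setdefault(name, {"status": None, "priority": None,
                                    "attempts": 0})
        ev = row["event"]
        if ev == "added":
            s["status"] = "pending"
        elif ev == "status":
            s["status"] = payload["to"]
        elif ev == "claimed":
            s["status"] = "running"
        elif ev == "lease_expired":
            s["status"] = "pending"
            s["attempts"] += 1
        elif ev == "attempt":
            s["attempts"] = payload["n"]
        elif ev == "priority":
            s["priority"] = payload["value"]
    return state
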