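"""Reading and normalising protein interaction data.

Accepts user-supplied CSV pair lists keyed on UniProt accessions, BioGRID
TAB3 exports restricted to physical-interaction evidence, and FASTA
sequence files; everything is normalised into an ``InteractionGraph`` of
unique proteins and unordered, deduplicated edges.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .errors import DataError, FormatError

__all__ = [
    "ProteinEntry",
    "InteractionEdge",
    "InteractionGraph",
    "BiogridFilter",
    "read_interactions_csv",
    "parse_biogrid_tab3",
    "load_sequences",
    "fetch_monomer_model",
]

log = logging.getLogger(__name__)

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

EVIDENCE_AFFINITY_CAPTURE = "affinity-capture"
EVIDENCE_TWO_HYBRID = "two-hybrid"
EVIDENCE_CO_PURIFICATION = "co-purification"
EVIDENCE_OTHER_PHYSICAL = "other-physical"

# BioGRID "Experimental System" names grouped into the evidence categories
# the pipeline filters on; unknown physical systems map to other-physical.
_BIOGRID_SYSTEM_MAP = {
    "affinity capture-ms": EVIDENCE_AFFINITY_CAPTURE,
    "affinity capture-western": EVIDENCE_AFFINITY_CAPTURE,
    "affinity capture-luminescence": EVIDENCE_AFFINITY_CAPTURE,
    "affinity capture-rna": EVIDENCE_AFFINITY_CAPTURE,
    "two-hybrid": EVIDENCE_TWO_HYBRID,
    "co-purification": EVIDENCE_CO_PURIFICATION,
    "co-fractionation": EVIDENCE_CO_PURIFICATION,
}


@dataclass
class ProteinEntry:
    """One protein keyed by UniProt accession, optionally carrying its
    sequence and per-residue pLDDT confidence (fractional, 0-1)."""

    uniprot_id: str
    gene_name: Optional[str] = None
    sequence: Optional[str] = None
    residue_plddt: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if not self.uniprot_id:
            raise DataError("uniprot_id must be non-empty")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - VALID_RESIDUES
            if bad:
                raise DataError(
                    f"{self.uniprot_id}: invalid residue codes {sorted(bad)}")
        if self.residue_plddt is not None:
            if self.sequence is not None and \
                    len(self.residue_plddt) != len(self.sequence):
                raise DataError(
                    f"{self.uniprot_id}: pLDDT length {len(self.residue_plddt)} "
                    f"!= sequence length {len(self.sequence)}")
            if any(not (0.0 <= p <= 1.0) for p in self.residue_plddt):
                raise DataError(f"{self.uniprot_id}: pLDDT values outside [0,1]")


@dataclass(frozen=True)
class InteractionEdge:
    """Unordered binary interaction: (a, b) == (b, a) after canonicalisation."""

    a: str
    b: str
    evidence_type: str = EVIDENCE_OTHER_PHYSICAL
    evidence_count: int = 1

    def __post_init__(self) -> None:
        lo, hi = sorted((self.a, self.b))
        object.__setattr__(self, "a", lo)
        object.__setattr__(self, "b", hi)
        if self.evidence_count < 0:
            raise DataError("evidence_count must be non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def is_self(self) -> bool:
        return self.a == self.b


class InteractionGraph:
    """Proteins as nodes, experimentally supported binary interactions as
    undirected edges. Duplicate edges merge; evidence counts accumulate."""

    def __init__(self) -> None:
        self.proteins: dict[str, ProteinEntry] = {}
        self._edges: dict[tuple[str, str], InteractionEdge] = {}

    @property
    def edges(self) -> list[InteractionEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def add_protein(self, entry: ProteinEntry) -> ProteinEntry:
        existing = self.proteins.get(entry.uniprot_id)
        if existing is None:
            self.proteins[entry.uniprot_id] = entry
            return entry
        if entry.sequence is not None:
            existing.sequence = entry.sequence
        if entry.gene_name is not None:
            existing.gene_name = entry.gene_name
        return existing

    def add_edge(self, edge: InteractionEdge) -> InteractionEdge:
        for end in edge.key:
            if end not in self.proteins:
                self.proteins[end] = ProteinEntry(end)
        prior = self._edges.get(edge.key)
        if prior is not None:
            merged = InteractionEdge(
                edge.a, edge.b,
                evidence_type=prior.evidence_type,
                evidence_count=prior.evidence_count + edge.evidence_count)
            self._edges[edge.key] = merged
            return merged
        self._edges[edge.key] = edge
        return edge

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self._edges

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b in self._edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return (set(self.proteins) == set(other.proteins)
                and self._edges == other._edges)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"InteractionGraph({len(self.proteins)} proteins, "
                f"{len(self._edges)} edges)")


def _open_text(source):
    """Accept a path (plain or .gz) or an already-open text stream."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        raw = path.open("rb").read()
        if raw[:2] == b"\x1f\x8b":
            raw = gzip.decompress(raw)
        return io.StringIO(raw.decode("utf-8"))
    return source


_HEADER_WORDS = {"protein", "uniprot", "interactor", "id", "source", "target",
                 "a", "b", "protein_a", "protein_b", "id_a", "id_b", "bait",
                 "prey", "accession"}
_ACCESSION_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9.\-]{0,23}$")


def _looks_like_header(fields: list[str]) -> bool:
    first_two = [f.strip() for f in fields[:2]]
    if any(f.lower() in _HEADER_WORDS for f in first_two):
        return True
    return any(f and not _ACCESSION_RE.match(f) for f in first_two)


def read_interactions_csv(source, header_present: Optional[bool] = None,
                          allow_self: bool = False) -> InteractionGraph:
    """Parse a two-column CSV of interacting UniProt accession pairs.

    Pairs are direction-normalised and deduplicated; every accession seen
    becomes a placeholder protein (sequence attached later from FASTA).
    When ``header_present`` is None the header is auto-detected by checking
    whether the first row's fields look like accessions. Self-interactions
    are rejected unless ``allow_self`` (homo-oligomers are expressed via
    stoichiometry downstream instead).
    """
    graph = InteractionGraph()
    stream = _open_text(source)
    reader = csv.reader(stream)
    rows = list(reader)
    # skip fully blank lines but keep original line numbers for messages
    numbered = [(i + 1, r) for i, r in enumerate(rows)
                if any(f.strip() for f in r)]
    if not numbered:
        return graph
    if header_present is None:
        header_present = _looks_like_header(numbered[0][1])
    if header_present:
        numbered = numbered[1:]
    for lineno, row in numbered:
        fields = [f.strip() for f in row if f.strip()]
        if len(fields) < 2:
            raise FormatError(
                f"line {lineno}: need at least two non-empty accession "
                f"fields, got {row!r}")
        a, b = fields[0], fields[1]
        if a == b and not allow_self:
            log.warning("line %d: self-interaction %s-%s rejected "
                        "(use stoichiometry for homo-oligomers)", lineno, a, b)
            continue
        graph.add_edge(InteractionEdge(a, b))
    return graph


@dataclass
class BiogridFilter:
    """Evidence filter for BioGRID rows: which physical-evidence categories
    to keep and the minimum number of supporting reports per pair.
    ``evidence_types=None`` admits every physical category."""

    evidence_types: Optional[set[str]] = None
    min_evidence_count: int = 1


_TAB3_ACCESSION_COLS = [
    ("SWISS-PROT Accessions Interactor A", "SWISS-PROT Accessions Interactor B"),
    ("Systematic Name Interactor A", "Systematic Name Interactor B"),
]


def parse_biogrid_tab3(source, filters: Optional[BiogridFilter] = None,
                       ) -> InteractionGraph:
    """Parse a BioGRID TAB3 export into an interaction graph.

    Only rows whose Experimental System Type is ``physical`` are admitted;
    rows are further restricted to the allowed evidence categories and the
    minimum per-pair report count in ``filters``. The per-pair
    ``evidence_count`` is the number of surviving supporting rows.
    SwissProt accession columns are preferred; systematic names are the
    fallback when an accession is missing (the pipeline key is UniProt).
    """
    filters = filters or BiogridFilter()
    stream = _open_text(source)
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    required = {"Experimental System", "Experimental System Type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"TAB3 input lacks mandatory columns: {sorted(missing)}")
    acc_cols = None
    for cols in _TAB3_ACCESSION_COLS:
        if set(cols) <= set(df.columns):
            acc_cols = cols
            break
    if acc_cols is None:
        raise FormatError(
            "TAB3 input lacks interactor accession columns "
            f"(looked for {_TAB3_ACCESSION_COLS})")

    def _acc(row, side: int) -> str:
        primary = row.get(_TAB3_ACCESSION_COLS[0][side], "")
        val = str(primary).split("|")[0].strip()
        if val and val != "-":
            return val
        fallback = row.get(_TAB3_ACCESSION_COLS[1][side], "")
        return str(fallback).split("|")[0].strip()

    pair_rows: dict[tuple[str, str], list[str]] = {}
    for _, row in df.iterrows():
        if str(row["Experimental System Type"]).strip().lower() != "physical":
            continue
        system = str(row["Experimental System"]).strip().lower()
        ev_type = _BIOGRID_SYSTEM_MAP.get(system, EVIDENCE_OTHER_PHYSICAL)
        if filters.evidence_types is not None and \
                ev_type not in filters.evidence_types:
            continue
        a, b = _acc(row, 0), _acc(row, 1)
        if not a or not b or a == "-" or b == "-" or a == b:
            continue
        pair_rows.setdefault(tuple(sorted((a, b))), []).append(ev_type)

    graph = InteractionGraph()
    for (a, b), types in sorted(pair_rows.items()):
        if len(types) < filters.min_evidence_count:
            continue
        graph.add_edge(InteractionEdge(a, b, evidence_type=types[0],
                                       evidence_count=len(types)))
    if not graph.edges:
        log.warning("no BioGRID rows survived the evidence filters")
    return graph


_PIPE_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def _accession_from_header(record_id: str) -> str:
    m = _PIPE_HEADER.match(record_id)
    return m.group(1) if m else record_id


def load_sequences(graph: InteractionGraph, fasta) -> list[str]:
    """Attach FASTA sequences to graph proteins by accession.

    Headers may be bare accessions or UniProt pipe-delimited
    (``sp|ACC|NAME``). Residues are uppercased. Returns the accessions still
    lacking a sequence afterwards; edges and protein count are untouched.
    """
    stream = _open_text(fasta)
    seen: dict[str, str] = {}
    for record in SeqIO.parse(stream, "fasta"):
        acc = _accession_from_header(record.id)
        seq = str(record.seq).upper()
        if acc in seen and seen[acc] != seq:
            raise DataError(
                f"FASTA contains conflicting sequences for accession {acc}")
        seen[acc] = seq
    for acc, seq in seen.items():
        if acc in graph.proteins:
            graph.proteins[acc].sequence = seq
    return sorted(a for a, p in graph.proteins.items() if p.sequence is None)


def fetch_monomer_model(uniprot_id: str, cache_dir,
                        fetcher: Optional[Callable[[str], Optional[bytes]]] = None,
                        ) -> Optional[Path]:
    """Return a cached monomer model file for an accession, fetching on miss.

    Network access is never hard-wired: on a cache miss the user-injected
    ``fetcher`` callable is consulted; it returns model-file bytes or None
    when the accession has no model in the source database. A raising
    fetcher is recorded as unavailable (warning) rather than fatal, since
    the pipeline can generate missing monomers itself.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"{uniprot_id}.pdb"
    if path.exists():
        return path
    if fetcher is None:
        return None
    try:
        payload = fetcher(uniprot_id)
    except Exception as exc:  # fetch failure is operational, not fatal
        log.warning("model fetch for %s failed (%s); monomer will be "
                    "generated in-pipeline", uniprot_id, exc)
        return None
    if payload is None:
        log.warning("no monomer model available for %s", uniprot_id)
        return None
    path.write_bytes(payload)
    return path
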