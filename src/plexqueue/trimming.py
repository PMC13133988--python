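"""pLDDT-based trimming of predicted monomer models.

Predicted monomer models carry a per-residue confidence (pLDDT) in the
B-factor column. Residues below a confidence cutoff — typically long
disordered tails and loops — dominate prediction run time without
contributing interface signal, so they are excised before complex
prediction. Only confidence thresholding is applied here; r.m.s.d.-based
domain splitting is deliberately not implemented (the cutoff flag name,
``--plddt-cutoff``, records that).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi

from .errors import DataError, DomainError, FormatError
from .interactome import ProteinEntry

__all__ = [
    "TrimmedModel",
    "read_plddt",
    "trim_by_plddt",
    "dataset_trim_report",
    "trim_structure_file",
    "write_segments_csv",
    "read_segments_csv",
    "write_trimmed_fasta",
]

log = logging.getLogger(__name__)


@dataclass
class TrimmedModel:
    """Result of trimming one monomer.

    kept_segments are 1-based inclusive residue ranges (internal masks are
    0-based half-open; the boundary is crossed exactly once, here).
    source_length is the untrimmed chain length, needed for pooled
    statistics even when everything was removed.
    """

    source_id: str
    kept_segments: list[tuple[int, int]]
    fraction_removed: float
    trimmed_sequence: str
    source_length: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.kept_segments:
            if start <= prev_end or end < start:
                raise DataError(
                    f"{self.source_id}: segments must be sorted and "
                    f"non-overlapping, got {self.kept_segments}")
            prev_end = end
        kept = sum(e - s + 1 for s, e in self.kept_segments)
        if kept != len(self.trimmed_sequence):
            raise DataError(
                f"{self.source_id}: trimmed sequence length "
                f"{len(self.trimmed_sequence)} != segment total {kept}")

    @property
    def kept_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.kept_segments)


def _structure_from(source) -> gemmi.Structure:
    if isinstance(source, (str, Path)):
        return gemmi.read_structure(str(source))
    text = source.read()
    # mmCIF content starts with data_; everything else is treated as PDB
    if text.lstrip().startswith("data_"):
        doc = gemmi.cif.read_string(text)
        return gemmi.make_structure_from_block(doc.sole_block())
    return gemmi.read_pdb_string(text)


def normalize_plddt(values: Sequence[float]) -> list[float]:
    """Map pLDDT to the fractional scale: values on 0-100 are divided by
    100; values already fractional are left alone."""
    vals = [float(v) for v in values]
    if any(v > 1.0 for v in vals):
        vals = [v / 100.0 for v in vals]
    return vals


def read_plddt(source, accession: Optional[str] = None) -> ProteinEntry:
    """Read a single-chain predicted model and extract per-residue pLDDT.

    The confidence is taken from the B-factor of each residue's CA atom
    (the AlphaFold-database convention) and normalised to [0,1]. The
    model's sequence is reconstructed from residue names.
    """
    st = _structure_from(source)
    st.setup_entities()
    if len(st) == 0:
        raise FormatError("model contains no coordinate model")
    model = st[0]
    chains = [ch for ch in model]
    if len(chains) != 1:
        raise FormatError(
            f"expected a single-chain monomer model, found {len(chains)} chains")
    chain = chains[0]
    seq = []
    plddt = []
    for i, res in enumerate(chain):
        info = gemmi.find_tabulated_residue(res.name)
        one = info.one_letter_code.upper() if info else "X"
        seq.append(one if one.isalpha() else "X")
        ca = res.find_atom("CA", "*")
        if ca is None:
            raise FormatError(
                f"residue {i + 1} ({res.name}) has no CA atom; cannot read "
                "its confidence value")
        plddt.append(ca.b_iso)
    if accession is None:
        accession = st.name or "model"
        if isinstance(source, (str, Path)):
            accession = Path(source).stem
    return ProteinEntry(uniprot_id=accession, sequence="".join(seq),
                        residue_plddt=normalize_plddt(plddt))


def _segments_from_mask(keep: Sequence[bool], min_segment: int
                        ) -> list[tuple[int, int]]:
    """0-based boolean keep-mask -> 1-based inclusive segments, dropping
    surviving runs shorter than min_segment."""
    segments: list[tuple[int, int]] = []
    start = None
    for i, k in enumerate([*keep, False]):
        if k and start is None:
            start = i
        elif not k and start is not None:
            if i - start >= min_segment:
                segments.append((start + 1, i))
            start = None
    return segments


def trim_by_plddt(entry: ProteinEntry, cutoff: float = 0.7,
                  min_segment: int = 5) -> TrimmedModel:
    """Drop residues whose pLDDT is below ``cutoff``; surviving runs shorter
    than ``min_segment`` residues are dropped too (single-residue islands
    left by hard thresholding are artifacts, not domains).

    An entry trimmed to nothing is returned as a valid empty model with a
    warning; the caller decides whether to skip the protein entirely.
    """
    if entry.residue_plddt is None:
        raise DomainError(f"{entry.uniprot_id}: no per-residue pLDDT loaded")
    if not (0.0 <= cutoff <= 1.0):
        raise DomainError(f"cutoff must be in [0,1], got {cutoff}")
    if min_segment < 1:
        raise DomainError(f"min_segment must be >= 1, got {min_segment}")
    n = len(entry.residue_plddt)
    keep = [p >= cutoff for p in entry.residue_plddt]
    segments = _segments_from_mask(keep, min_segment)
    kept = sum(e - s + 1 for s, e in segments)
    seq = entry.sequence or "X" * n
    trimmed_seq = "".join(seq[s - 1:e] for s, e in segments)
    if kept == 0:
        log.warning("%s: trimming removed every residue (cutoff=%.2f)",
                    entry.uniprot_id, cutoff)
    return TrimmedModel(
        source_id=entry.uniprot_id,
        kept_segments=segments,
        fraction_removed=1.0 - kept / n,
        trimmed_sequence=trimmed_seq,
        source_length=n,
    )


def dataset_trim_report(models: Iterable[TrimmedModel]) -> dict:
    """Aggregate removal statistics over a trimmed dataset.

    The pooled fraction weights proteins by length (total residues removed
    over total residues); the mean is the unweighted per-protein average.
    """
    models = list(models)
    if not models:
        raise DomainError("dataset_trim_report needs at least one model")
    total = sum(m.source_length for m in models)
    removed = sum(m.source_length - m.kept_residues for m in models)
    per_protein = {m.source_id: m.fraction_removed for m in models}
    return {
        "per_protein": per_protein,
        "pooled_fraction_removed": removed / total,
        "mean_fraction_removed": sum(per_protein.values()) / len(per_protein),
        "n_proteins": len(models),
        "total_residues": total,
        "removed_residues": removed,
    }


def trim_structure_file(in_path, out_path, cutoff: float = 0.7,
                        min_segment: int = 5) -> TrimmedModel:
    """Trim a monomer model file and write the trimmed PDB.

    Original residue numbering is preserved in the output so kept segments
    remain identifiable after a round trip through the file.
    """
    entry = read_plddt(in_path)
    trimmed = trim_by_plddt(entry, cutoff=cutoff, min_segment=min_segment)
    keep_positions = set()
    for s, e in trimmed.kept_segments:
        keep_positions.update(range(s, e + 1))
    st = _structure_from(in_path)
    model = st[0]
    chain = model[0]
    for i in reversed(range(len(chain))):
        if (i + 1) not in keep_positions:
            del chain[i]
    st.write_pdb(str(out_path))
    return trimmed


def write_segments_csv(models: Iterable[TrimmedModel], stream) -> None:
    """Sidecar CSV of kept segments: accession, start, end (1-based)."""
    writer = csv.writer(stream)
    writer.writerow(["accession", "start", "end"])
    for m in sorted(models, key=lambda m: m.source_id):
        for s, e in m.kept_segments:
            writer.writerow([m.source_id, s, e])


def read_segments_csv(stream) -> dict[str, list[tuple[int, int]]]:
    reader = csv.reader(stream)
    header = next(reader, None)
    if header != ["accession", "start", "end"]:
        raise FormatError(f"unexpected segments CSV header: {header}")
    out: dict[str, list[tuple[int, int]]] = {}
    for acc, s, e in reader:
        out.setdefault(acc, []).append((int(s), int(e)))
    return out


def write_trimmed_fasta(models: Iterable[TrimmedModel], stream) -> None:
    for m in sorted(models, key=lambda m: m.source_id):
        stream.write(f">{m.source_id} trimmed fraction_removed="
                     f"{m.fraction_removed:.3f}\n{m.trimmed_sequence}\n")
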