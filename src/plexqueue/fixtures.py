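"""Synthetic interactomes, planted-complex truth tables and model files.

Everything the pipeline consumes can be generated here, so the whole tool
is exercisable with no database download and no GPU:

* ``make_interactome`` — Erdős–Rényi background interactions plus planted
  "true" complexes whose pairwise edges are forced in, with a truth table
  mapping every planted subcomplex to a high ipTM (0.85) for the planted
  simulator backend (baseline elsewhere: 0.2).
* ``make_star_interactome`` — a bait-centred topology as produced by
  co-IP/MS experiments: one bait connected to each partner, no
  partner-partner edges.
* ``make_model_file`` — AlphaFold-database-style single-chain PDB with
  per-residue confidence in the B-factor column, drawn from a well-folded
  (22% of residues below pLDDT 0.7), disordered (59% below) or mixed (40%)
  profile. The two regimes mirror a structured organellar interactome vs a
  disorder-rich transcription-factor interactome.

All randomness is derived from the fixture seed; identical specs produce
identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .enumeration import ComplexSpec, subcomplexes_of
from .errors import DomainError
from .interactome import InteractionEdge, InteractionGraph, ProteinEntry

__all__ = [
    "FixtureSpec",
    "PLDDT_PROFILES",
    "make_interactome",
    "make_star_interactome",
    "make_model_file",
    "random_sequence",
    "truth_table_for",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PLANTED_SCORE = 0.85
BASELINE_SCORE = 0.2

# fraction of residues below pLDDT 0.7 per profile: well-folded mirrors a
# structured (organellar/metabolic) interactome, disordered mirrors a
# eukaryotic transcription-factor interactome.
PLDDT_PROFILES = {"well-folded": 0.22, "disordered": 0.59, "mixed": 0.40}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic interactome."""

    n_proteins: int
    edge_density: float = 0.1
    planted_complexes: list[ComplexSpec] = field(default_factory=list)
    seed: int = 0
    sequence_length_range: tuple[int, int] = (80, 200)
    plddt_profile: str = "mixed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_density <= 1.0):
            raise DomainError(
                f"edge_density must be in [0,1], got {self.edge_density}")
        if self.plddt_profile not in PLDDT_PROFILES:
            raise DomainError(f"unknown pLDDT profile {self.plddt_profile!r}")
        for c in self.planted_complexes:
            if c.size > self.n_proteins:
                raise DomainError(
                    f"planted complex {c.canonical_name} larger than the "
                    f"interactome ({c.size} > {self.n_proteins})")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def protein_names(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def truth_table_for(planted: list[ComplexSpec],
                    score: float = PLANTED_SCORE) -> dict[str, float]:
    """Score table covering every sub-multiset (size >= 2) of each planted
    complex, including the complex itself."""
    table: dict[str, float] = {}
    for comp in planted:
        table[comp.canonical_name] = score
        for level in range(2, comp.size):
            for sub in subcomplexes_of(comp, level):
                table[sub.canonical_name] = score
    return table


def make_interactome(spec: FixtureSpec
                     ) -> tuple[InteractionGraph, dict[str, float]]:
    """Synthetic interactome plus the planted-complex truth table.

    Background edges are sampled Erdős–Rényi at ``edge_density``; every
    pairwise edge inside a planted complex is forced in so planted
    assemblies are reachable by connected-subgraph enumeration. Sequences
    are random with lengths uniform in ``sequence_length_range``.
    """
    rng = np.random.default_rng(spec.seed)
    names = protein_names(spec.n_proteins)
    graph = InteractionGraph()
    lo, hi = spec.sequence_length_range
    for name in names:
        length = int(rng.integers(lo, hi + 1))
        graph.add_protein(ProteinEntry(name, sequence=random_sequence(rng, length)))
    for a, b in combinations(names, 2):
        if rng.random() < spec.edge_density:
            graph.add_edge(InteractionEdge(a, b))
    for comp in spec.planted_complexes:
        members = sorted(set(comp.members))
        for a, b in combinations(members, 2):
            if not graph.has_edge(a, b):
                graph.add_edge(InteractionEdge(a, b))
    return graph, truth_table_for(spec.planted_complexes)


def make_star_interactome(n_partners: int, bait: str = "BAIT",
                          seed: int = 0,
                          sequence_length_range: tuple[int, int] = (80, 200),
                          ) -> InteractionGraph:
    """Bait-centred interactome: the bait interacts with each of
    ``n_partners`` leaf proteins; leaves do not interact with each other
    (the co-IP/MS topology before any complex evidence)."""
    if n_partners < 1:
        raise DomainError("need at least one partner")
    rng = np.random.default_rng(seed)
    graph = InteractionGraph()
    lo, hi = sequence_length_range
    graph.add_protein(ProteinEntry(
        bait, sequence=random_sequence(rng, int(rng.integers(lo, hi + 1)))))
    for name in protein_names(n_partners):
        graph.add_protein(ProteinEntry(
            name, sequence=random_sequence(rng, int(rng.integers(lo, hi + 1)))))
        graph.add_edge(InteractionEdge(bait, name))
    return graph


def sample_plddt(n: int, profile: str, rng: np.random.Generator) -> np.ndarray:
    """Per-residue confidence from a two-component mixture.

    Each residue is low-confidence with the profile's probability; low
    values come from N(0.45, 0.1) truncated to [0, 0.7), high values from
    N(0.88, 0.05) truncated to [0.7, 1], so the below-0.7 fraction is an
    exact binomial draw at the profile rate.
    """
    frac_low = PLDDT_PROFILES[profile]
    low_mask = rng.random(n) < frac_low

    def _trunc(mean, sd, lo, hi, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)

    out = np.empty(n)
    n_low = int(low_mask.sum())
    out[low_mask] = _trunc(0.45, 0.10, 0.0, 0.69999, n_low)
    out[~low_mask] = _trunc(0.88, 0.05, 0.7, 1.0, n - n_low)
    return out


_PDB_ATOM = ("ATOM  {serial:5d}  CA  {resname:<3s} A{resseq:4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C\n")

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def make_model_file(entry: ProteinEntry, profile: str = "mixed",
                    seed: int = 0, path=None) -> str:
    """AFDB-style single-chain CA-trace PDB with per-residue confidence
    (0-100 scale, two decimals) in the B-factor column. Returns the PDB
    text; also writes it when ``path`` is given."""
    if entry.sequence is None:
        raise DomainError(f"{entry.uniprot_id}: sequence required")
    rng = np.random.default_rng(seed)
    plddt = sample_plddt(len(entry.sequence), profile, rng)
    lines = [f"HEADER    PREDICTED MODEL                         {entry.uniprot_id}\n"]
    for i, (aa, p) in enumerate(zip(entry.sequence, plddt), start=1):
        lines.append(_PDB_ATOM.format(
            serial=i, resname=_ONE_TO_THREE.get(aa, "UNK"), resseq=i,
            x=3.8 * i, y=0.0, z=0.0, occ=1.0, b=round(100 * p, 2)))
    lines.append("TER\nEND\n")
    text = "".join(lines)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text
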