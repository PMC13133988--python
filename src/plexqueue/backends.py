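"""Scoring contract between the scheduler and structure-prediction engines.

The scheduler only ever sees ``PredictionResult`` objects produced by a
scorer callable; which engine produced them is irrelevant. Three backends
are provided:

* ``MockBackend`` — deterministic, hash-derived scores; used for plumbing
  tests and dry runs.
* ``PlantedBackend`` — simulator with a truth table: subcomplexes of
  planted "true" complexes score high, everything else scores a low
  baseline, optionally with clipped Gaussian noise. Used to check that the
  priority/pruning machinery recovers known assemblies.
* ``ColabFoldAdapter`` — file-level adapter (input writer + score-JSON
  parser) for a ColabFold-style engine. It never launches the engine; it
  raises ``BackendUnavailableError`` if asked to score without one.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .enumeration import ComplexSpec
from .errors import BackendUnavailableError, DomainError, FormatError

__all__ = [
    "PredictionResult",
    "BackendConfig",
    "MockBackend",
    "PlantedBackend",
    "ColabFoldAdapter",
    "make_backend",
    "score_complex",
    "write_engine_input",
    "write_engine_fasta",
    "parse_engine_scores",
    "select_rank1_file",
]


@dataclass
class PredictionResult:
    """Scores for one evaluated complex.

    iptm is the interface confidence in [0,1] used for prioritisation; ptm
    the global-topology confidence; mean_plddt the mean per-residue local
    confidence; pae, when present, the square matrix of expected positional
    errors in angstroms (side = total residues over all chains).
    """

    complex: ComplexSpec
    iptm: float
    ptm: float
    mean_plddt: Optional[float] = None
    pae: Optional[np.ndarray] = None
    model_ref: Optional[str] = None
    model_rank: int = 1

    def __post_init__(self) -> None:
        for name in ("iptm", "ptm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"{name}={v} outside [0,1]")
        if self.mean_plddt is not None and not (0.0 <= self.mean_plddt <= 1.0):
            raise FormatError(f"mean_plddt={self.mean_plddt} outside [0,1]")
        if self.pae is not None:
            pae = np.asarray(self.pae, dtype=float)
            if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
                raise FormatError(f"PAE matrix is not square: {pae.shape}")
            if (pae < 0).any():
                raise FormatError("PAE matrix has negative entries")
            self.pae = pae
        if self.model_rank < 1:
            raise FormatError("model_rank must be >= 1")


@dataclass
class BackendConfig:
    """Declarative backend selection; ``seed`` fixes all stochastic
    behaviour of the simulated backends."""

    kind: str = "mock"
    seed: int = 0
    noise_sd: float = 0.0
    truth_table: Optional[Mapping[str, float]] = None
    baseline: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("mock", "planted", "colabfold-adapter"):
            raise DomainError(f"unknown backend kind {self.kind!r}")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


def _hash_unit(*parts) -> float:
    """Platform-independent map of arbitrary parts to [0,1): first 8 bytes
    of a SHA-256 digest scaled by 2^64."""
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:8], "big") / 2.0 ** 64


class MockBackend:
    """Deterministic pseudo-scorer: ipTM is a hash of (canonical_name, seed).

    Keeps a dispatch log in ``calls`` so tests can assert that poisoned
    complexes never reach the backend.
    """

    def __init__(self, seed: int = 0,
                 overrides: Optional[Mapping[str, float]] = None):
        self.seed = seed
        self.overrides = dict(overrides or {})
        self.calls: list[str] = []

    def score(self, spec: ComplexSpec) -> PredictionResult:
        name = spec.canonical_name
        self.calls.append(name)
        iptm = self.overrides.get(name, _hash_unit("iptm", name, self.seed))
        return PredictionResult(
            complex=spec,
            iptm=iptm,
            ptm=_hash_unit("ptm", name, self.seed),
            mean_plddt=_hash_unit("plddt", name, self.seed),
        )

    __call__ = score


class PlantedBackend:
    """Truth-table simulator: a complex found in the truth table scores its
    table value, anything else the low baseline, plus clipped Gaussian
    noise of sd ``noise_sd``. Noise is derived per complex from
    (seed, canonical_name), so results do not depend on call order."""

    def __init__(self, truth_table: Mapping[str, float], seed: int = 0,
                 noise_sd: float = 0.0, baseline: float = 0.2):
        self.truth_table = dict(truth_table)
        self.seed = seed
        self.noise_sd = noise_sd
        self.baseline = baseline
        self.calls: list[str] = []

    def noiseless(self, spec: ComplexSpec) -> float:
        return self.truth_table.get(spec.canonical_name, self.baseline)

    def score(self, spec: ComplexSpec) -> PredictionResult:
        name = spec.canonical_name
        self.calls.append(name)
        base = self.noiseless(spec)
        if self.noise_sd > 0:
            # per-complex substream: deterministic and order-independent
            sub = int(_hash_unit("noise", name, self.seed) * 2**31)
            rng = np.random.default_rng(sub)
            base += rng.normal(0.0, self.noise_sd)
        iptm = float(min(1.0, max(0.0, base)))
        return PredictionResult(
            complex=spec,
            iptm=iptm,
            ptm=iptm,
            mean_plddt=iptm,
        )

    __call__ = score


class ColabFoldAdapter:
    """File-level adapter for a ColabFold-style engine.

    ``prepare`` writes the engine's input file for a complex; ``collect``
    parses the engine's score JSON back into a PredictionResult. Direct
    scoring requires an engine, which this environment does not assume.
    """

    def __init__(self, sequences: Mapping[str, str], work_dir):
        self.sequences = dict(sequences)
        self.work_dir = Path(work_dir)

    def prepare(self, spec: ComplexSpec) -> Path:
        return write_engine_input(spec, self.sequences, self.work_dir)

    def collect(self, spec: ComplexSpec) -> PredictionResult:
        paths = sorted(self.work_dir.glob(f"{spec.canonical_name}*score*rank*.json"))
        if not paths:
            raise FormatError(
                f"no score files found for {spec.canonical_name} in {self.work_dir}")
        best = select_rank1_file(paths)
        with best.open() as fh:
            result = parse_engine_scores(fh, spec)
        result.model_ref = str(best)
        return result

    def score(self, spec: ComplexSpec) -> PredictionResult:
        raise BackendUnavailableError(
            "no structure-prediction engine is wired to this adapter; "
            "use prepare()/collect() around an external engine run")

    __call__ = score


def make_backend(config: BackendConfig,
                 sequences: Optional[Mapping[str, str]] = None,
                 work_dir=None):
    """Instantiate the backend described by a BackendConfig."""
    if config.kind == "mock":
        return MockBackend(seed=config.seed)
    if config.kind == "planted":
        return PlantedBackend(config.truth_table or {}, seed=config.seed,
                              noise_sd=config.noise_sd, baseline=config.baseline)
    return ColabFoldAdapter(sequences or {}, work_dir or ".")


def score_complex(sequences: Sequence[tuple[str, str]],
                  backend) -> PredictionResult:
    """Score one complex given its (accession, sequence) chains.

    ``backend`` may be a BackendConfig or an instantiated backend object.
    """
    if len(sequences) < 2:
        raise DomainError("a complex needs at least 2 chains to score")
    if any(not seq for _, seq in sequences):
        raise DomainError("empty chain sequence")
    spec = ComplexSpec.from_iterable(acc for acc, _ in sequences)
    if isinstance(backend, BackendConfig):
        backend = make_backend(backend, sequences=dict(sequences))
    return backend.score(spec)


def write_engine_input(spec: ComplexSpec, sequences: Mapping[str, str],
                       out_dir) -> Path:
    """Write a single-query engine input CSV (``id,sequence`` header, chains
    joined with ':') for one complex. Member order is canonical, and copies
    are repeated per the spec's multiset, so permuted construction of the
    same complex yields byte-identical files."""
    chains = []
    for acc in spec.members:
        seq = sequences.get(acc)
        if not seq:
            raise DomainError(f"no sequence available for member {acc!r}")
        chains.append(seq)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{spec.canonical_name}.csv"
    path.write_text(f"id,sequence\n{spec.canonical_name},{':'.join(chains)}\n")
    return path


def write_engine_fasta(spec: ComplexSpec, sequences: Mapping[str, str],
                       out_dir) -> Path:
    """Equivalent engine input as multi-record FASTA (one record per chain
    copy, canonical order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{spec.canonical_name}.fasta"
    lines = []
    for i, acc in enumerate(spec.members):
        seq = sequences.get(acc)
        if not seq:
            raise DomainError(f"no sequence available for member {acc!r}")
        lines.append(f">{spec.canonical_name}|chain{i + 1}|{acc}\n{seq}\n")
    path.write_text("".join(lines))
    return path


_RANK_RE = re.compile(r"rank[_\-]?0*(\d+)")


def select_rank1_file(paths: Iterable[Path]) -> Path:
    """Pick the rank-1 score file from a set of per-model score files
    following the ``..._rank_001_...`` naming convention."""
    ranked = []
    for p in paths:
        m = _RANK_RE.search(p.name)
        ranked.append((int(m.group(1)) if m else 1, p.name, p))
    ranked.sort()
    return ranked[0][2]


def parse_engine_scores(source, spec: ComplexSpec) -> PredictionResult:
    """Parse a ColabFold-style score JSON for one complex.

    Requires iptm and ptm (a multimer score file without iptm is an error,
    never silently 0); the per-residue plddt array and pae matrix are
    optional. plddt values on the 0-100 scale are normalised to fractions.
    """
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = json.load(source)
    if "iptm" not in data:
        raise FormatError(
            f"score file for {spec.canonical_name} lacks the iptm field")
    if "ptm" not in data:
        raise FormatError(
            f"score file for {spec.canonical_name} lacks the ptm field")
    iptm, ptm = float(data["iptm"]), float(data["ptm"])
    mean_plddt = None
    if data.get("plddt"):
        arr = np.asarray(data["plddt"], dtype=float)
        if arr.max() > 1.0:
            arr = arr / 100.0
        mean_plddt = float(arr.mean())
    pae = None
    if data.get("pae") is not None:
        pae = np.asarray(data["pae"], dtype=float)
    m = _RANK_RE.search(getattr(source, "name", "") or "")
    rank = int(m.group(1)) if m else 1
    return PredictionResult(complex=spec, iptm=iptm, ptm=ptm,
                            mean_plddt=mean_plddt, pae=pae, model_rank=rank)
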