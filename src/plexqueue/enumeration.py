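"""Expansion of an interaction graph into a queue of candidate complexes.

A candidate complex is a multiset of protein accessions (``ComplexSpec``).
Binary interactions are expanded into all candidate assemblies up to a
configured maximum size, either as connected induced subgraphs of the
interaction graph (default) or as unrestricted all-vs-all combinations,
optionally restricted to complexes containing a designated target protein.

The closed-form count of potential complexes for an interactome of ``n``
proteins with ``r`` members per complex is the binomial coefficient
C(n, r) = n!/(r!(n-r)!); summed over a size range this grows past a
trillion for a 40-member interactome, which is why the downstream
scheduler prunes rather than computes the full space.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Optional

from .errors import DomainError
from .interactome import InteractionGraph

__all__ = [
    "ComplexSpec",
    "EnumerationConfig",
    "count_potential_complexes",
    "enumerate_supercomplexes",
    "apply_stoichiometry",
    "subcomplexes_of",
    "export_queue_csv",
]

CONNECTED_SUBGRAPH = "connected-subgraph"
ALL_VS_ALL = "all-vs-all"


@dataclass(frozen=True, order=True)
class ComplexSpec:
    """Canonical multiset of member accessions defining one candidate complex.

    ``members`` is a sorted tuple with copies expanded, so two specs compare
    equal iff their multisets are equal, regardless of construction order.
    """

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.members))
        if len(ordered) < 2:
            raise DomainError(f"a complex needs >= 2 members, got {len(ordered)}")
        object.__setattr__(self, "members", ordered)

    @classmethod
    def of(cls, *members: str) -> "ComplexSpec":
        return cls(tuple(members))

    @classmethod
    def from_iterable(cls, members: Iterable[str]) -> "ComplexSpec":
        return cls(tuple(members))

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def canonical_name(self) -> str:
        return "_".join(self.members)

    def counter(self) -> Counter:
        return Counter(self.members)

    def contains(self, other: "ComplexSpec", strict: bool = True) -> bool:
        """Multiset containment: every copy of every member of *other* is here."""
        if strict and self == other:
            return False
        return not (other.counter() - self.counter())

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


@dataclass
class EnumerationConfig:
    """Parameters controlling queue expansion.

    max_size defaults to 4, the complex-size cap used throughout the
    benchmark campaigns; connectivity_rule decides whether a candidate must
    be a connected induced subgraph of the interaction graph.
    """

    max_size: int = 4
    required_member: Optional[str] = None
    connectivity_rule: str = CONNECTED_SUBGRAPH
    allow_homo: bool = False
    stoichiometry: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_size < 2:
            raise DomainError(f"max_size must be >= 2, got {self.max_size}")
        if self.connectivity_rule not in (CONNECTED_SUBGRAPH, ALL_VS_ALL):
            raise DomainError(f"unknown connectivity rule {self.connectivity_rule!r}")


def count_potential_complexes(n: int, r_min: int, r_max: int) -> int:
    """Exact number of distinct complexes of size r_min..r_max from n proteins.

    Computes sum_{r=r_min}^{r_max} C(n, r) with arbitrary-precision integers;
    no floating point is involved, so the 40-protein case returns the exact
    1,099,511,627,735 rather than an approximation.
    """
    if not (0 <= r_min <= r_max):
        raise DomainError(f"need 0 <= r_min <= r_max, got {r_min}..{r_max}")
    if r_max > n:
        raise DomainError(f"r_max={r_max} exceeds interactome size n={n}")
    return sum(math.comb(n, r) for r in range(r_min, r_max + 1))


def _connected_subsets(graph: InteractionGraph, max_size: int,
                       required: Optional[str]) -> Iterator[frozenset]:
    """Yield node subsets (2..max_size) inducing a connected subgraph.

    Grows a frontier of connected sets by one adjacent node at a time; any
    connected set of size k+1 contains a connected size-k subset (remove a
    leaf of a spanning tree), so every target set is reached. When a required
    member is set, growth starts only from pairs containing it — removing
    spanning-tree leaves other than the required node preserves both
    connectivity and membership, so completeness is retained.
    """
    g = graph.to_networkx()
    pairs = set()
    for a, b in g.edges():
        if required is not None and required not in (a, b):
            continue
        pairs.add(frozenset((a, b)))
    frontier = pairs
    seen: set[frozenset] = set()
    size = 2
    while frontier and size <= max_size:
        new: set[frozenset] = set()
        for s in frontier:
            if s not in seen:
                seen.add(s)
                yield s
            if size < max_size:
                neigh = set()
                for v in s:
                    neigh.update(g[v])
                for w in neigh - s:
                    new.add(s | {w})
        frontier = new
        size += 1


def enumerate_supercomplexes(graph: InteractionGraph,
                             config: EnumerationConfig) -> set[ComplexSpec]:
    """Expand a binary interaction graph into the full candidate-complex queue.

    Under the connected-subgraph rule every node subset whose induced
    subgraph is connected becomes a candidate; under all-vs-all every subset
    does. Candidates are capped at ``config.max_size`` members and, in target
    mode, restricted to those containing ``config.required_member``.
    """
    if not graph.proteins:
        raise DomainError("cannot enumerate over an empty interaction graph")
    req = config.required_member
    if req is not None and req not in graph.proteins:
        raise DomainError(f"required member {req!r} is not a node of the graph")

    out: set[ComplexSpec] = set()
    if config.connectivity_rule == ALL_VS_ALL:
        nodes = sorted(graph.proteins)
        if req is not None:
            others = [n for n in nodes if n != req]
            for r in range(1, config.max_size):
                for combo in combinations(others, r):
                    out.add(ComplexSpec.from_iterable((req, *combo)))
        else:
            for r in range(2, config.max_size + 1):
                for combo in combinations(nodes, r):
                    out.add(ComplexSpec.from_iterable(combo))
    else:
        for subset in _connected_subsets(graph, config.max_size, req):
            out.add(ComplexSpec.from_iterable(subset))

    if config.stoichiometry:
        out = {apply_stoichiometry(c, {k: v for k, v in config.stoichiometry.items()
                                       if k in c.members})
               for c in out}
    return out


def apply_stoichiometry(complex_: ComplexSpec,
                        copies: Mapping[str, int]) -> ComplexSpec:
    """Repeat members of a complex according to known copy numbers.

    A 1:1 stoichiometry (all copies 1, or an empty map) returns an equal
    spec; homo-oligomeric members are expressed by listing the accession
    multiple times in the resulting multiset.
    """
    counts = complex_.counter()
    for acc, k in copies.items():
        if acc not in counts:
            raise DomainError(f"{acc!r} is not a member of {complex_.canonical_name}")
        if k < 1:
            raise DomainError(f"copy number for {acc!r} must be >= 1, got {k}")
        counts[acc] = k
    members: list[str] = []
    for acc, k in counts.items():
        members.extend([acc] * k)
    return ComplexSpec.from_iterable(members)


def subcomplexes_of(complex_: ComplexSpec, level: int) -> set[ComplexSpec]:
    """All distinct size-``level`` sub-multisets of a complex's members."""
    if not (2 <= level < complex_.size):
        raise DomainError(
            f"level must be in [2, {complex_.size - 1}], got {level}")
    return {ComplexSpec.from_iterable(c)
            for c in combinations(complex_.members, level)}


def export_queue_csv(specs: Iterable[ComplexSpec], stream) -> int:
    """Write the queue as CSV (canonical_name,size,members) in deterministic
    order: size ascending, then canonical name. Returns the row count."""
    rows = sorted(specs, key=lambda c: (c.size, c.canonical_name))
    stream.write("canonical_name,size,members\n")
    for c in rows:
        stream.write(f"{c.canonical_name},{c.size},{';'.join(c.members)}\n")
    return len(rows)
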