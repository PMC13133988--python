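"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own enumeration/scheduling
code paths: enumeration is checked against an exhaustive subset scan with
networkx connectivity, and scheduler priorities against a direct
recomputation over the containment lattice.
"""

from itertools import combinations

import networkx as nx
import pytest

from plexqueue.enumeration import ComplexSpec
from plexqueue.interactome import InteractionEdge, InteractionGraph
from plexqueue.scheduler import MemoryStore, Status


@pytest.fixture
def path_graph():
    """A-B, B-C: the minimal bridged topology (A and C never touch)."""
    g = InteractionGraph()
    g.add_edge(InteractionEdge("A", "B"))
    g.add_edge(InteractionEdge("B", "C"))
    return g


@pytest.fixture
def triangle_graph():
    g = InteractionGraph()
    for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
        g.add_edge(InteractionEdge(a, b))
    return g


def graph_from_edges(pairs):
    g = InteractionGraph()
    for a, b in pairs:
        g.add_edge(InteractionEdge(a, b))
    return g


def brute_force_connected_subsets(graph: InteractionGraph, max_size: int,
                                  required=None):
    """Exhaustive scan of every node subset, testing induced-subgraph
    connectivity with networkx."""
    g = graph.to_networkx()
    nodes = sorted(g.nodes)
    out = set()
    for r in range(2, max_size + 1):
        for combo in combinations(nodes, r):
            if required is not None and required not in combo:
                continue
            sub = g.subgraph(combo)
            if nx.is_connected(sub):
                out.add(ComplexSpec.from_iterable(combo))
    return out


def brute_force_priorities(store, threshold):
    """Expected priority of every pending record: the max ipTM over its
    strictly contained done subcomplexes that met the threshold, or None."""
    done = [(r.complex, r.result.iptm) for r in store.records(Status.DONE)]
    expected = {}
    for rec in store.records(Status.PENDING):
        best = None
        for sub, iptm in done:
            if iptm >= threshold and rec.complex.contains(sub, strict=True):
                if best is None or iptm > best:
                    best = iptm
        expected[rec.canonical_name] = best
    return expected


def brute_force_dead_ends(store, threshold, completed_level):
    """Pending records above the completed level with no threshold-meeting
    scored subcomplex: the set that dead-end elimination must poison."""
    expected = brute_force_priorities(store, threshold)
    return {name for name, pri in expected.items()
            if store.get(name).size > completed_level
            and (pri is None or pri < threshold)}


def populate(specs):
    store = MemoryStore()
    for spec in specs:
        store.add(spec)
    return store
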