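"""Shared fixtures: tiny hand-built pathway graphs with known structure."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from subspia.kgml_io import GeneGraph, parse_edge_list


def make_graph(edges, nodes=(), pathway_id="test"):
    """Build a GeneGraph from (src, tgt, relation) or (src, tgt) tuples
    (bare pairs default to activation)."""
    from subspia.kgml_io import RELATION_BETA, _collapse_edges

    raw = []
    for e in edges:
        if len(e) == 2:
            s, t, rel = e[0], e[1], "activation"
        else:
            s, t, rel = e
        raw.append((s, t, rel, RELATION_BETA[rel]))
    collapsed = _collapse_edges(raw)
    all_nodes = set(nodes) | {g for e in collapsed for g in (e[0], e[1])}
    return GeneGraph(pathway_id, pathway_id, frozenset(all_nodes), collapsed)


@pytest.fixture
def worked_example_graph():
    """Seven-gene network whose trimmed MST drops exactly one node.

    Signature genes {16, 17, 20, 22, 24}; non-signature {19, 21}.  Node 19
    sits on the only short 17..24 route so growth admits it, but the MST can
    reach 24 through 22 instead, stranding 19 as a non-signature leaf; 21 is
    an interior connector that must survive trimming.
    """
    edges = [
        ("16", "17"),
        ("17", "19"),
        ("19", "24"),
        ("17", "21"),
        ("21", "20"),
        ("21", "22"),
        ("22", "24"),
    ]
    return make_graph(edges, pathway_id="worked")


@pytest.fixture
def worked_example_signature():
    return frozenset({"16", "17", "20", "22", "24"})


@pytest.fixture
def path_graph_sxs():
    """s1 - x - s2 path: one non-signature gene between two DEGs."""
    return make_graph([("s1", "x"), ("x", "s2")])


def brute_force_mst_weight(wg) -> float:
    """Minimum spanning-tree weight by enumerating all edge subsets of size
    |V| - 1 (oracle; graphs must be small)."""
    n = len(wg.nodes)
    best = None
    for combo in itertools.combinations(wg.edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(wg.nodes)
        g.add_edges_from((u, v) for u, v, _w in combo)
        if nx.is_connected(g):
            total = sum(w for _u, _v, w in combo)
            if best is None or total < best:
                best = total
    assert best is not None, "graph is disconnected"
    return best


def sequential_grow_signature_partition(graph, signature, n_s, order, rule="intermediates"):
    """Order-dependent reference implementation of node-set growth.

    Seeds a set with each not-yet-covered signature node in the given order
    and repeatedly admits any signature node connected to the set by a
    qualifying shortest path.  Returns the partition of signature nodes as a
    frozenset of frozensets (the non-signature membership is order-dependent
    and is checked separately).
    """
    from subspia.locator import _admitting_path

    g = graph.to_undirected()
    sigs = [s for s in order if s in signature and s in graph.nodes]
    signature = frozenset(signature)
    remaining = list(sigs)
    parts = []
    while remaining:
        seed = remaining.pop(0)
        part = {seed}
        changed = True
        while changed:
            changed = False
            for v in list(remaining):
                for u in sorted(part):
                    if _admitting_path(g, u, v, signature, n_s, rule) is not None:
                        part.add(v)
                        remaining.remove(v)
                        changed = True
                        break
        parts.append(frozenset(part))
    return frozenset(parts)


__all__ = [
    "make_graph",
    "brute_force_mst_weight",
    "sequential_grow_signature_partition",
]
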