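"""Locating DEG-dense subpathways with a weighted minimal spanning tree.

Differentially expressed genes (signature nodes) tend to cluster in a local
region of a signaling pathway.  The locator first grows node sets: two
signature nodes are linked when a shortest undirected path between them
carries at most ``n_s`` non-signature intermediates, and the non-signature
nodes of one deterministic admitting path join the set.  Each grown set is
then converted to an undirected weighted graph where edges between signature
nodes cost 1 and edges touching non-signature nodes cost more (the penalty
shrinks when the non-signature node touches many signature nodes), a minimal
spanning tree is extracted with Kruskal's algorithm, and non-signature
leaves are trimmed away.  The surviving tree is the subpathway: maximal in
signature nodes, minimal in non-signature ones.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx

from .kgml_io import DEGInput, GeneGraph

logger = logging.getLogger(__name__)

__all__ = [
    "NodeSet",
    "WeightedSubgraph",
    "Subpathway",
    "grow_node_sets",
    "build_weighted_subgraph",
    "kruskal_mst",
    "trim_mst",
    "locate_subpathways",
]

DistanceRule = Literal["intermediates", "edges"]

#: Cap on enumerated equal-length shortest paths per node pair; pathway
#: graphs are sparse so this is never hit in practice.
_MAX_PATHS = 50_000


@dataclass(frozen=True)
class NodeSet:
    """A grown, connected set of pathway genes around clustered DEGs."""

    pathway_id: str
    members: frozenset[str]
    signature_members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.signature_members <= self.members:
            raise ValueError("signature members must be a subset of members")


@dataclass(frozen=True)
class WeightedSubgraph:
    """Undirected weighted view of a node set, ready for MST extraction.

    ``k`` maps every node to its number of signature neighbours within the
    induced subgraph; edge weights are >= 1 and equal 1 exactly when both
    endpoints are signature nodes.
    """

    nodes: frozenset[str]
    signature: frozenset[str]
    edges: tuple[tuple[str, str, float], ...]  # (u, v, w) with u < v
    k: dict[str, int]


@dataclass(frozen=True)
class Subpathway:
    """A (possibly trimmed) spanning tree over a node set."""

    pathway_id: str
    members: frozenset[str]
    signature_members: frozenset[str]
    tree_edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.signature_members <= self.members:
            raise ValueError("signature members must be a subset of members")
        if self.members:
            g = nx.Graph()
            g.add_nodes_from(self.members)
            g.add_edges_from(self.tree_edges)
            if len(self.tree_edges) != len(self.members) - 1 or not nx.is_connected(g):
                raise ValueError("tree_edges do not form a spanning tree of members")

    @property
    def n_signature(self) -> int:
        return len(self.signature_members)

    @property
    def n_total(self) -> int:
        return len(self.members)


def _admitting_path(
    g: nx.Graph,
    u: str,
    v: str,
    signature: frozenset[str],
    n_s: int,
    distance_rule: DistanceRule,
) -> list[str] | None:
    """Deterministic admitting shortest path between signature nodes, or None.

    Under the ``intermediates`` rule a pair qualifies when some shortest
    (minimum-edge) path carries at most ``n_s`` non-signature intermediate
    nodes; under the ``edges`` rule when the shortest-path length is at most
    ``n_s + 1`` edges.  Among qualifying shortest paths the lexicographically
    smallest node sequence is returned, so growth is order-independent.
    """
    try:
        paths = itertools.islice(nx.all_shortest_paths(g, u, v), _MAX_PATHS)
        candidates = []
        for p in paths:
            if distance_rule == "edges":
                if len(p) - 1 <= n_s + 1:
                    candidates.append(p)
            else:
                n_nonsig = sum(1 for x in p[1:-1] if x not in signature)
                if n_nonsig <= n_s:
                    candidates.append(p)
    except nx.NetworkXNoPath:
        return None
    if not candidates:
        return None
    return min(candidates)


def grow_node_sets(
    graph: GeneGraph,
    signature: Iterable[str],
    n_s: int = 4,
    distance_rule: DistanceRule = "intermediates",
) -> list[NodeSet]:
    """Grow disjoint node sets covering every signature gene in the graph.

    Growth is formulated as the transitive closure of the pairwise admission
    relation, so the result does not depend on which signature node seeds a
    set.  Signature genes absent from the graph are skipped with a log
    message; an empty signature yields an empty list.
    """
    if n_s < 0:
        raise ValueError("n_s must be non-negative")
    signature = frozenset(signature)
    sig_in_graph = sorted(signature & graph.nodes)
    skipped = signature - graph.nodes
    if skipped:
        logger.debug(
            "grow_node_sets(%s): %d signature gene(s) absent from graph",
            graph.pathway_id, len(skipped),
        )
    if not sig_in_graph:
        return []

    g = graph.to_undirected()
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = ci

    link = nx.Graph()
    link.add_nodes_from(sig_in_graph)
    admitted_paths: dict[tuple[str, str], list[str]] = {}
    for u, v in itertools.combinations(sig_in_graph, 2):
        if comp_of[u] != comp_of[v]:
            continue
        path = _admitting_path(g, u, v, signature, n_s, distance_rule)
        if path is not None:
            link.add_edge(u, v)
            admitted_paths[(u, v)] = path

    node_sets = []
    for comp in nx.connected_components(link):
        members = set(comp)
        for (u, v), path in admitted_paths.items():
            if u in comp:
                members.update(path)
        node_sets.append(
            NodeSet(
                pathway_id=graph.pathway_id,
                members=frozenset(members),
                signature_members=frozenset(comp),
            )
        )
    node_sets.sort(key=lambda s: min(s.signature_members))
    return node_sets


def build_weighted_subgraph(
    graph: GeneGraph,
    node_set: NodeSet,
    k_zero_penalty: float = 2.0,
) -> WeightedSubgraph:
    """Weight the undirected subgraph induced by a node set.

    W(u, v) = 1 when both endpoints are signature nodes, 1 + 1/k_v when only
    v is non-signature, and 1 + 1/k_u + 1/k_v when both are, where k_x counts
    the signature nodes adjacent to x inside the induced subgraph.  A
    non-signature node with no signature neighbour (possible for large n_s)
    contributes the finite ``k_zero_penalty`` instead of 1/0, which keeps it
    strictly costlier than any k >= 1 node.
    """
    members = node_set.members
    sig = node_set.signature_members
    sub = graph.to_undirected().subgraph(members)
    k = {x: sum(1 for y in sub.neighbors(x) if y in sig) for x in members}

    def penalty(x: str) -> float:
        return 1.0 / k[x] if k[x] > 0 else k_zero_penalty

    edges = []
    for u, v in sub.edges():
        u, v = min(u, v), max(u, v)
        if u in sig and v in sig:
            w = 1.0
        elif u in sig:
            w = 1.0 + penalty(v)
        elif v in sig:
            w = 1.0 + penalty(u)
        else:
            w = 1.0 + penalty(u) + penalty(v)
        edges.append((u, v, w))
    return WeightedSubgraph(
        nodes=frozenset(members),
        signature=frozenset(sig),
        edges=tuple(sorted(edges)),
        k=k,
    )


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def kruskal_mst(wg: WeightedSubgraph, pathway_id: str = "") -> Subpathway:
    """Minimal spanning tree by Kruskal's algorithm.

    Edges are taken in order of (weight, min endpoint, max endpoint), which
    makes the tree deterministic under weight ties.  The input must be
    connected.
    """
    order = sorted(wg.edges, key=lambda e: (e[2], e[0], e[1]))
    uf = _UnionFind(wg.nodes)
    tree = []
    for u, v, _w in order:
        if uf.union(u, v):
            tree.append((u, v))
    if len(tree) != len(wg.nodes) - 1:
        raise ValueError("weighted subgraph is not connected")
    return Subpathway(
        pathway_id=pathway_id,
        members=wg.nodes,
        signature_members=wg.signature,
        tree_edges=tuple(tree),
    )


def mst_total_weight(wg: WeightedSubgraph, tree_edges: Sequence[tuple[str, str]]) -> float:
    """Total weight of a set of edges of ``wg`` (helper for diagnostics)."""
    wmap = {(u, v): w for u, v, w in wg.edges}
    return sum(wmap[(min(u, v), max(u, v))] for u, v in tree_edges)


def trim_mst(tree: Subpathway) -> Subpathway:
    """Iteratively remove non-signature leaves until every leaf is a DEG.

    Signature nodes are never removed; interior non-signature nodes that keep
    the tree connected survive.  Idempotent.
    """
    g = nx.Graph()
    g.add_nodes_from(tree.members)
    g.add_edges_from(tree.tree_edges)
    sig = tree.signature_members
    while True:
        removable = [
            x for x in g.nodes
            if x not in sig and g.degree(x) <= 1 and g.number_of_nodes() > 1
        ]
        if not removable:
            break
        g.remove_nodes_from(removable)
    return Subpathway(
        pathway_id=tree.pathway_id,
        members=frozenset(g.nodes),
        signature_members=sig,
        tree_edges=tuple(sorted(tuple(sorted(e)) for e in g.edges)),
    )


def locate_subpathways(
    graph: GeneGraph,
    deg: DEGInput,
    n_s: int = 4,
    distance_rule: DistanceRule = "intermediates",
    k_zero_penalty: float = 2.0,
    min_signature_nodes: int = 1,
) -> list[Subpathway]:
    """Full subpathway location: grow, weight, span, trim.

    Returns one trimmed spanning tree per grown node set (singleton signature
    genes become single-node subpathways), deterministically ordered.
    """
    subpathways = []
    for node_set in grow_node_sets(graph, deg.signature, n_s, distance_rule):
        if len(node_set.members) == 1:
            sp = Subpathway(
                pathway_id=graph.pathway_id,
                members=node_set.members,
                signature_members=node_set.signature_members,
                tree_edges=(),
            )
        else:
            wg = build_weighted_subgraph(graph, node_set, k_zero_penalty)
            sp = trim_mst(kruskal_mst(wg, pathway_id=graph.pathway_id))
        if sp.n_signature >= min_signature_nodes:
            subpathways.append(sp)
    return subpathways
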