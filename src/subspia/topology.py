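"""Pathway-level crosstalk network and topology statistics.

Signaling pathways reference each other (KGML ``map`` entries and
``maplink`` relations); those cross-references define an undirected
pathway-pathway network.  For a subset of pathways — typically those called
significant by an identification method — this module computes the average
whole-network degree and betweenness of the subset, the average clustering
coefficient of the subset within its neighbor-inclusive induced subgraph,
and a permutation p-value for the average degree against uniformly random
same-size subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .kgml_io import kgml_pathway_refs

__all__ = [
    "PathwayNetwork",
    "TopologySummary",
    "build_pathway_network",
    "pathway_network_from_edge_list",
    "write_pathway_network",
    "topology_summary",
    "topology_report",
]


@dataclass(frozen=True)
class PathwayNetwork:
    """Simple undirected graph over pathway identifiers."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # each pair stored as (min, max)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != (min(u, v), max(u, v)):
                raise ValueError(f"edge not normalized: ({u!r}, {v!r})")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint not a node: ({u!r}, {v!r})")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class TopologySummary:
    subset_size: int
    avg_degree: float
    avg_clustering: float
    avg_betweenness: float
    degree_p_value: float
    edge_rule: str = "maplink"


def build_pathway_network(
    kgml_documents: Iterable[str | bytes],
    rule: str = "maplink",
    min_shared_genes: int = 1,
) -> PathwayNetwork:
    """Build the pathway network from a collection of KGML documents.

    ``rule = "maplink"`` links two pathways when either document
    cross-references the other (map entries / maplink relations);
    ``rule = "shared_genes"`` links them when they share at least
    ``min_shared_genes`` genes.
    """
    parsed = [kgml_pathway_refs(doc) for doc in kgml_documents]
    ids = frozenset(pid for pid, _refs, _genes in parsed)
    edges: set[tuple[str, str]] = set()
    if rule == "maplink":
        for pid, refs, _genes in parsed:
            for ref in refs:
                if ref in ids and ref != pid:
                    edges.add((min(pid, ref), max(pid, ref)))
    elif rule == "shared_genes":
        genes = {pid: g for pid, _refs, g in parsed}
        for i, a in enumerate(sorted(ids)):
            for b in sorted(ids)[i + 1:]:
                if len(genes[a] & genes[b]) >= min_shared_genes:
                    edges.add((a, b))
    else:
        raise ValueError(f"unknown edge rule {rule!r}")
    return PathwayNetwork(nodes=ids, edges=frozenset(edges))


def pathway_network_from_edge_list(text: str) -> PathwayNetwork:
    """Read a pathway network from a TSV of ``pathway_a<TAB>pathway_b`` rows
    (single-token lines declare isolated pathways; ``#`` comments)."""
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            nodes.add(parts[0])
            continue
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two pathway ids, got {line!r}")
        a, b = parts
        nodes.update((a, b))
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return PathwayNetwork(nodes=frozenset(nodes), edges=frozenset(edges))


def write_pathway_network(net: PathwayNetwork) -> str:
    g = net.to_networkx()
    lines = [n for n in sorted(net.nodes) if g.degree(n) == 0]
    lines += [f"{u}\t{v}" for u, v in sorted(net.edges)]
    return "\n".join(lines) + "\n"


def topology_summary(
    net: PathwayNetwork,
    subset: Iterable[str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    neighbor_inclusive: bool = True,
    edge_rule: str = "maplink",
) -> TopologySummary:
    """Topology statistics of a pathway subset within the whole network.

    Degree and (unnormalized shortest-path) betweenness are whole-network
    quantities averaged over the subset.  Clustering is the Watts-Strogatz
    local coefficient averaged over subset nodes, computed on the subgraph
    induced by the subset plus its direct neighbors (the subset alone when
    ``neighbor_inclusive`` is false).  The degree p-value is the fraction of
    ``n_perm`` uniformly random same-size subsets whose average degree
    reaches the observed one, with add-one smoothing.
    """
    subset = sorted(set(subset))
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = set(subset) - net.nodes
    if missing:
        raise ValueError(f"subset pathways absent from network: {sorted(missing)}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    g = net.to_networkx()
    degree = dict(g.degree())
    avg_degree = float(np.mean([degree[p] for p in subset]))
    betweenness = nx.betweenness_centrality(g, normalized=False)
    avg_betweenness = float(np.mean([betweenness[p] for p in subset]))

    region = set(subset)
    if neighbor_inclusive:
        for p in subset:
            region.update(g.neighbors(p))
    clustering = nx.clustering(g.subgraph(region), nodes=subset)
    avg_clustering = float(np.mean([clustering[p] for p in subset]))

    nodes = sorted(net.nodes)
    deg_arr = np.array([degree[n] for n in nodes], dtype=float)
    k = len(subset)
    picks = np.argsort(rng.random((n_perm, len(nodes))), axis=1)[:, :k]
    null_means = deg_arr[picks].mean(axis=1)
    exceed = int(np.sum(null_means >= avg_degree - 1e-12))
    p_value = (1 + exceed) / (n_perm + 1)

    return TopologySummary(
        subset_size=k,
        avg_degree=avg_degree,
        avg_clustering=avg_clustering,
        avg_betweenness=avg_betweenness,
        degree_p_value=p_value,
        edge_rule=edge_rule,
    )


def topology_report(summaries: dict[str, TopologySummary]) -> pd.DataFrame:
    """Tabulate summaries per method/subset name (Deg, p-value, Clu, Bet)."""
    rows = [
        {
            "method": name,
            "n_pathways": s.subset_size,
            "avg_degree": s.avg_degree,
            "degree_p_value": s.degree_p_value,
            "avg_clustering": s.avg_clustering,
            "avg_betweenness": s.avg_betweenness,
            "edge_rule": s.edge_rule,
        }
        for name, s in summaries.items()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "method", "n_pathways", "avg_degree", "degree_p_value",
            "avg_clustering", "avg_betweenness", "edge_rule",
        ],
    )
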