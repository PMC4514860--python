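"""Synthetic pathway graphs and DEG inputs with known planted structure.

Signaling pathways are sparse directed graphs dominated by linear cascades
with occasional shortcuts.  The generator emulates that shape: a chain
backbone over a random gene permutation plus uniformly random shortcut
edges, with most edges carrying a signed interaction (activation or
inhibition) and the rest neutral.  A differential-expression experiment is
emulated by planting a connected module of coherently shifted genes (grown
by a random walk, matching the locality assumption of subpathway analysis)
on top of sparse background DEGs.

Everything is deterministic given a seed, so end-to-end recovery behaviour
is reproducible across platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .kgml_io import DEGInput, GeneGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "generate_pathway",
    "plant_de_module",
    "simulate_cohort",
]

#: Relation mix for generated edges: share of signed edges that are
#: activations (the rest are inhibitions); unsigned edges are
#: binding/association.  Signaling maps are dominated by signed regulation,
#: hence the high default signed fraction used by generate_pathway.
ACTIVATION_SHARE = 0.7


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one planted differential-expression experiment."""

    pathway_id: str
    planted_module: frozenset[str]
    effect_size: float
    noise_sd: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "pathway_id": self.pathway_id,
                "planted_module": sorted(self.planted_module),
                "effect_size": self.effect_size,
                "noise_sd": self.noise_sd,
                "seed": self.seed,
            },
            indent=2,
        )


def _relation_for(rng: np.random.Generator, signed_fraction: float) -> tuple[str, int]:
    if rng.random() < signed_fraction:
        if rng.random() < ACTIVATION_SHARE:
            return "activation", +1
        return "inhibition", -1
    return "binding/association", 0


def generate_pathway(
    n_genes: int,
    edge_density: float = 0.05,
    signed_fraction: float = 0.9,
    seed: int = 0,
    pathway_id: str | None = None,
    gene_prefix: str | None = None,
) -> GeneGraph:
    """Generate a connected, sparse, directed pathway gene graph.

    A spanning chain over a random permutation guarantees connectivity;
    shortcut edges are added until ``edge_density`` (relative to the
    n*(n-1) possible directed edges) is reached.  When the density implies
    fewer edges than the chain needs, the chain is kept and the shortfall
    logged.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    prefix = gene_prefix if gene_prefix is not None else "g"
    pid = pathway_id if pathway_id is not None else f"syn{seed:04d}"
    genes = [f"{prefix}{i:03d}" for i in range(n_genes)]

    order = rng.permutation(n_genes)
    existing: set[tuple[int, int]] = set()
    edges: list[tuple[str, str, str, int]] = []
    for a, b in zip(order[:-1], order[1:]):
        rel, beta = _relation_for(rng, signed_fraction)
        edges.append((genes[a], genes[b], rel, beta))
        existing.add((int(a), int(b)))

    target = round(edge_density * n_genes * (n_genes - 1))
    if target < n_genes - 1:
        logger.debug(
            "generate_pathway: density %.3f below spanning-chain minimum; "
            "keeping %d chain edges", edge_density, n_genes - 1,
        )
    while len(edges) < target:
        a, b = (int(x) for x in rng.integers(0, n_genes, size=2))
        if a == b or (a, b) in existing:
            continue
        rel, beta = _relation_for(rng, signed_fraction)
        edges.append((genes[a], genes[b], rel, beta))
        existing.add((a, b))

    return GeneGraph(pid, pid, frozenset(genes), tuple(sorted(edges)))


def plant_de_module(
    graph: GeneGraph,
    module_size: int,
    effect: float = 3.0,
    background_de_rate: float = 0.02,
    noise_sd: float = 0.3,
    seed: int = 0,
    universe: frozenset[str] | None = None,
) -> tuple[DEGInput, SyntheticTruth]:
    """Plant a connected, coherently shifted DE module into a pathway.

    The module is grown by a random walk on the undirected view of the graph
    (so it is always connected); its genes get dE = s*effect + N(0, noise_sd)
    for a single random module sign s.  Every other universe gene becomes a
    background DEG independently with probability ``background_de_rate`` and
    dE ~ N(0, 1).  ``module_size = 0`` plants nothing.
    """
    if module_size > graph.n_nodes:
        raise ValueError("module_size exceeds the number of pathway genes")
    rng = np.random.default_rng(seed)
    universe = frozenset(universe) if universe is not None else graph.nodes

    module: set[str] = set()
    if module_size > 0:
        und = graph.to_undirected()
        start = sorted(graph.nodes)[int(rng.integers(0, graph.n_nodes))]
        comp = set(nx.node_connected_component(und, start))
        if len(comp) < module_size:
            raise ValueError(
                "module_size exceeds the connected component of the start node"
            )
        module.add(start)
        while len(module) < module_size:
            frontier = sorted(
                {nb for g in module for nb in und.neighbors(g)} - module
            )
            module.add(frontier[int(rng.integers(0, len(frontier)))])

    delta_e: dict[str, float] = {}
    sign = 1.0 if rng.random() < 0.5 else -1.0
    for g in sorted(module):
        delta_e[g] = sign * effect + rng.normal(0.0, noise_sd)
    for g in sorted(universe - module):
        if rng.random() < background_de_rate:
            delta_e[g] = rng.normal(0.0, 1.0)

    deg = DEGInput(
        universe=universe,
        analyzed=frozenset(delta_e),
        delta_e=delta_e,
    )
    truth = SyntheticTruth(
        pathway_id=graph.pathway_id,
        planted_module=frozenset(module),
        effect_size=effect,
        noise_sd=noise_sd,
        seed=seed,
    )
    return deg, truth


def simulate_cohort(
    n_pathways: int = 4,
    n_genes: int = 50,
    edge_density: float = 0.05,
    module_size: int = 6,
    effect: float = 3.0,
    background_de_rate: float = 0.02,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, GeneGraph], DEGInput, SyntheticTruth]:
    """Simulate one study: several pathways, a module planted in the first.

    Pathways get disjoint gene namespaces; the shared universe is the union
    of all pathway genes.  Background DEGs fall across the whole universe,
    so pathways other than the first act as decoys.
    """
    rng = np.random.default_rng(seed)
    graphs: dict[str, GeneGraph] = {}
    for i in range(n_pathways):
        g = generate_pathway(
            n_genes,
            edge_density=edge_density,
            seed=int(rng.integers(0, 2**31 - 1)),
            pathway_id=f"synP{i:02d}",
            gene_prefix=f"P{i:02d}_",
        )
        graphs[g.pathway_id] = g
    universe = frozenset().union(*(g.nodes for g in graphs.values()))
    planted_graph = graphs["synP00"]
    deg, truth = plant_de_module(
        planted_graph,
        module_size=module_size,
        effect=effect,
        background_de_rate=background_de_rate,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        universe=universe,
    )
    return graphs, deg, truth
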