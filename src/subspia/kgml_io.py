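"""Parsing of KGML pathway documents and plain-text fixtures into gene graphs.

KEGG distributes each signaling pathway as a KGML (XML) document whose
``entry`` elements are genes, gene families, protein complexes, compounds or
cross-references to other pathway maps, and whose ``relation`` elements are
typed, directed interactions between entries.  For impact analysis we need a
graph whose nodes are *single genes* and whose edges carry a signed unit
weight beta (activation-like = +1, inhibition-like = -1, neutral = 0), so
multi-gene entries are expanded to the Cartesian product of gene-level edges
and compound-mediated gene->compound->gene chains are contracted to direct
gene->gene edges.

This module also reads/writes a tab-separated edge-list dialect used by the
synthetic-data generator and the test fixtures, and reads tables of
differentially expressed genes (DEGs).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneGraph",
    "DEGInput",
    "RELATION_BETA",
    "KGMLError",
    "KGMLParseError",
    "KGMLStructureError",
    "EdgeListError",
    "DEGTableError",
    "parse_kgml",
    "kgml_pathway_refs",
    "parse_edge_list",
    "write_edge_list",
    "write_kgml",
    "read_deg_table",
    "subpathway_report",
    "score_report",
]

#: Signed unit weight per KGML relation subtype.  Activation-like subtypes
#: propagate a positive perturbation, inhibition-like a negative one; every
#: other interaction type is kept as an (unsigned) edge with beta = 0 so it
#: still contributes to connectivity but not to the perturbation flow.
RELATION_BETA: dict[str, int] = {
    "activation": +1,
    "expression": +1,
    "inhibition": -1,
    "repression": -1,
    "binding/association": 0,
    "phosphorylation": 0,
    "dephosphorylation": 0,
    "ubiquitination": 0,
    "methylation": 0,
    "glycosylation": 0,
    "indirect effect": 0,
    "state change": 0,
    "dissociation": 0,
    "missing interaction": 0,
    "compound": 0,
    "hidden compound": 0,
    "maplink": 0,
    "unknown": 0,
}


class KGMLError(ValueError):
    """Base error for malformed pathway inputs."""


class KGMLParseError(KGMLError):
    """The document is not well-formed XML."""


class KGMLStructureError(KGMLError):
    """The XML is well-formed but violates the KGML structure."""


class EdgeListError(ValueError):
    """A line of the edge-list dialect could not be interpreted."""


class DEGTableError(ValueError):
    """The DEG table violates its contract."""


@dataclass(frozen=True)
class GeneGraph:
    """Directed gene-level network of one pathway.

    Edges are ``(source, target, relation_type, beta)`` with beta in
    {-1, 0, +1}.  Parallel edges between the same ordered gene pair have
    already been collapsed (beta = clipped sum) and self-loops removed.
    """

    pathway_id: str
    pathway_name: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str, str, int], ...]

    def __post_init__(self) -> None:
        for s, t, _rel, beta in self.edges:
            if s == t:
                raise ValueError(f"self-loop on {s!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge endpoint not in nodes: ({s!r}, {t!r})")
            if beta not in (-1, 0, 1):
                raise ValueError(f"beta outside {{-1,0,1}}: {beta!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_directed(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id)
        g.add_nodes_from(sorted(self.nodes))
        for s, t, rel, beta in self.edges:
            g.add_edge(s, t, relation=rel, beta=beta)
        return g

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for s, t, _rel, _beta in self.edges:
            g.add_edge(s, t)
        return g

    def induced(self, members: Iterable[str]) -> "GeneGraph":
        """Subgraph induced by ``members`` (edge attributes preserved)."""
        keep = frozenset(members)
        missing = keep - self.nodes
        if missing:
            raise ValueError(f"genes not in graph: {sorted(missing)}")
        edges = tuple(e for e in self.edges if e[0] in keep and e[1] in keep)
        return GeneGraph(self.pathway_id, self.pathway_name, keep, edges)


def _collapse_edges(
    raw: Iterable[tuple[str, str, str, int]]
) -> tuple[tuple[str, str, str, int], ...]:
    """Drop self-loops and collapse parallel edges.

    The perturbation model indexes beta by ordered gene pair, so multiple
    relations between the same pair become one edge whose beta is the sum
    clipped to {-1, 0, +1} and whose relation label joins the distinct types.
    """
    acc: dict[tuple[str, str], tuple[list[str], int]] = {}
    for s, t, rel, beta in raw:
        if s == t:
            continue
        rels, bsum = acc.setdefault((s, t), ([], 0))
        if rel not in rels:
            rels.append(rel)
        acc[(s, t)] = (rels, bsum + beta)
    out = []
    for (s, t), (rels, bsum) in acc.items():
        beta = max(-1, min(1, bsum))
        out.append((s, t, "+".join(sorted(rels)), beta))
    return tuple(sorted(out))


def _beta_for(subtype: str, beta_table: Mapping[str, int]) -> int:
    return beta_table.get(subtype, 0)


def _parse_kgml_tree(text: str | bytes) -> etree._Element:
    data = text.encode() if isinstance(text, str) else text
    try:
        return etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        # report a byte offset alongside lxml's line/column position
        line, col = exc.position
        offset = 0
        for i, ln in enumerate(data.split(b"\n"), start=1):
            if i == line:
                offset += col
                break
            offset += len(ln) + 1
        raise KGMLParseError(
            f"malformed XML at byte offset {offset} (line {line}, column {col}): {exc.msg}"
        ) from exc


def _kgml_entries(root: etree._Element) -> dict[str, dict]:
    entries: dict[str, dict] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "gene")
        name = entry.get("name", "")
        genes: list[str]
        if etype == "group":
            genes = []  # resolved in a second pass from <component> children
        else:
            genes = name.split()
        entries[eid] = {
            "type": etype,
            "name": name,
            "genes": genes,
            "components": [c.get("id") for c in entry.findall("component")],
        }
    # resolve groups (complexes): union of member entries' genes
    for eid, e in entries.items():
        if e["type"] == "group":
            genes: list[str] = []
            for cid in e["components"]:
                if cid not in entries:
                    raise KGMLStructureError(
                        f"group entry {eid!r} references undefined entry id {cid!r}"
                    )
                genes.extend(entries[cid]["genes"])
            e["genes"] = genes
    return entries


def parse_kgml(
    text: str | bytes,
    beta_table: Mapping[str, int] | None = None,
) -> GeneGraph:
    """Parse a KGML document into a gene-level :class:`GeneGraph`.

    Multi-gene entries (families, complexes) yield the Cartesian product of
    gene-level edges.  A relation whose subtype is activation/expression maps
    to beta = +1, inhibition/repression to -1, anything else to 0.
    Gene -> compound -> gene chains are contracted to gene -> gene edges that
    carry the downstream relation's subtype.
    """
    beta_table = RELATION_BETA if beta_table is None else beta_table
    root = _parse_kgml_tree(text)
    pathway_id = root.get("name", "unknown")
    pathway_name = root.get("title", pathway_id)
    entries = _kgml_entries(root)

    gene_like = {"gene", "ortholog", "group", "enzyme"}
    nodes: set[str] = set()
    for e in entries.values():
        if e["type"] in gene_like:
            nodes.update(e["genes"])

    raw_edges: list[tuple[str, str, str, int]] = []
    # compound-mediated chains: entry-level in/out relations per compound entry
    cpd_in: dict[str, list[tuple[str, str]]] = {}  # compound id -> [(src entry, subtype)]
    cpd_out: dict[str, list[tuple[str, str]]] = {}  # compound id -> [(dst entry, subtype)]

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        for eid in (e1, e2):
            if eid not in entries:
                raise KGMLStructureError(
                    f"relation references undefined entry id {eid!r}"
                )
        subtypes = [st.get("name", "unknown") for st in rel.findall("subtype")]
        if not subtypes:
            subtypes = ["unknown"]
        # one representative subtype: prefer a signed one, then first listed
        subtype = next((s for s in subtypes if _beta_for(s, beta_table) != 0), subtypes[0])
        t1, t2 = entries[e1]["type"], entries[e2]["type"]
        if t1 == "compound" or t2 == "compound":
            if t1 == "compound" and t2 != "compound":
                cpd_out.setdefault(e1, []).append((e2, subtype))
            elif t2 == "compound" and t1 != "compound":
                cpd_in.setdefault(e2, []).append((e1, subtype))
            continue
        if t1 == "map" or t2 == "map":
            continue  # pathway cross-references carry no gene edge
        beta = _beta_for(subtype, beta_table)
        for g1 in entries[e1]["genes"]:
            for g2 in entries[e2]["genes"]:
                raw_edges.append((g1, g2, subtype, beta))

    # contract gene -> compound -> gene, keeping the downstream subtype
    for cid, outs in cpd_out.items():
        for src_entry, _sub_in in cpd_in.get(cid, []):
            for dst_entry, sub_out in outs:
                beta = _beta_for(sub_out, beta_table)
                for g1 in entries[src_entry]["genes"]:
                    for g2 in entries[dst_entry]["genes"]:
                        raw_edges.append((g1, g2, sub_out, beta))

    edges = _collapse_edges(raw_edges)
    nodes.update(g for e in edges for g in (e[0], e[1]))
    return GeneGraph(pathway_id, pathway_name, frozenset(nodes), edges)


def kgml_pathway_refs(text: str | bytes) -> tuple[str, frozenset[str], frozenset[str]]:
    """Extract ``(pathway_id, referenced pathway ids, gene set)`` from KGML.

    References are ``map``-type entries and endpoints of ``maplink``
    relations; they drive the pathway-level crosstalk network.
    """
    root = _parse_kgml_tree(text)
    pathway_id = root.get("name", "unknown")
    entries = _kgml_entries(root)
    refs: set[str] = set()
    genes: set[str] = set()
    for e in entries.values():
        if e["type"] == "map":
            refs.update(e["name"].split())
        elif e["type"] in {"gene", "ortholog", "group", "enzyme"}:
            genes.update(e["genes"])
    refs.discard(pathway_id)
    return pathway_id, frozenset(refs), frozenset(genes)


def parse_edge_list(
    text: str,
    pathway_id: str = "edge_list",
    pathway_name: str | None = None,
    beta_table: Mapping[str, int] | None = None,
) -> GeneGraph:
    """Parse the tab-separated fixture dialect into a :class:`GeneGraph`.

    Each line is ``source<TAB>relation<TAB>target``; a single-token line
    declares an isolated node; ``#`` starts a comment.  The relation
    vocabulary is the KGML subtype table; unknown tokens raise
    :class:`EdgeListError` naming the line.
    """
    beta_table = RELATION_BETA if beta_table is None else beta_table
    nodes: set[str] = set()
    raw: list[tuple[str, str, str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            nodes.add(parts[0])
            continue
        if len(parts) != 3:
            raise EdgeListError(
                f"line {lineno}: expected 'source<TAB>relation<TAB>target', got {line!r}"
            )
        src, rel, tgt = parts
        if rel not in beta_table:
            raise EdgeListError(f"line {lineno}: unknown relation {rel!r}")
        nodes.update((src, tgt))
        raw.append((src, tgt, rel, beta_table[rel]))
    edges = _collapse_edges(raw)
    return GeneGraph(
        pathway_id, pathway_name if pathway_name is not None else pathway_id,
        frozenset(nodes), edges,
    )


def write_edge_list(graph: GeneGraph) -> str:
    """Serialize a graph to the edge-list dialect (round-trips with
    :func:`parse_edge_list` up to line order)."""
    lines = [f"# pathway: {graph.pathway_id}"]
    touched = {g for e in graph.edges for g in (e[0], e[1])}
    for node in sorted(graph.nodes - touched):
        lines.append(node)
    for s, t, rel, _beta in graph.edges:
        # collapsed multi-relation labels are written with their first type
        lines.append(f"{s}\t{rel.split('+')[0]}\t{t}")
    return "\n".join(lines) + "\n"


def write_kgml(graph: GeneGraph) -> str:
    """Emit a minimal well-formed KGML document for ``graph``.

    One single-gene entry per node and one relation per edge; parsing the
    result with :func:`parse_kgml` reproduces the graph.
    """
    root = etree.Element(
        "pathway", name=graph.pathway_id, title=graph.pathway_name, org="syn"
    )
    ids = {g: str(i + 1) for i, g in enumerate(sorted(graph.nodes))}
    for gene, eid in ids.items():
        etree.SubElement(root, "entry", id=eid, name=gene, type="gene")
    for s, t, rel, _beta in graph.edges:
        r = etree.SubElement(
            root, "relation", entry1=ids[s], entry2=ids[t], type="PPrel"
        )
        etree.SubElement(r, "subtype", name=rel.split("+")[0], value="")
    return etree.tostring(root, pretty_print=True, encoding="unicode")


@dataclass(frozen=True)
class DEGInput:
    """Differential-expression input for one analysis run.

    ``universe`` is the background of all measurable genes (size *m*),
    ``analyzed`` the genes submitted for analysis (size *n*), and ``delta_e``
    maps each signature gene (DEG) to its signed log fold-change.
    """

    universe: frozenset[str]
    analyzed: frozenset[str]
    delta_e: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.analyzed <= self.universe:
            extra = sorted(self.analyzed - self.universe)[:5]
            raise ValueError(f"analyzed genes outside universe, e.g. {extra}")
        if not set(self.delta_e) <= self.analyzed:
            extra = sorted(set(self.delta_e) - self.analyzed)[:5]
            raise ValueError(f"signature genes outside analyzed set, e.g. {extra}")
        for g, v in self.delta_e.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite expression change for {g!r}: {v!r}")

    @property
    def m(self) -> int:
        return len(self.universe)

    @property
    def n(self) -> int:
        return len(self.analyzed)

    @property
    def signature(self) -> frozenset[str]:
        return frozenset(self.delta_e)


def read_deg_table(
    text: str,
    universe: Iterable[str],
    adj_p_threshold: float | None = None,
) -> DEGInput:
    """Read a tab-separated DEG table into a :class:`DEGInput`.

    Required columns: ``gene_id``, ``log_fc``; optional ``adj_p``.  When
    ``adj_p_threshold`` is given and an ``adj_p`` column exists, only rows at
    or below the threshold enter the signature while every retained row
    enters the analyzed set; otherwise all rows are signature genes.  Genes
    absent from ``universe`` are excluded with a logged warning; duplicate
    gene ids and non-numeric fold-changes are errors.
    """
    universe = frozenset(universe)
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log_fc"):
        if col not in df.columns:
            raise DEGTableError(f"missing required column {col!r}")
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        raise DEGTableError(f"duplicate gene ids: {sorted(set(dupes))}")
    log_fc = pd.to_numeric(df["log_fc"], errors="coerce")
    bad = df.index[log_fc.isna()].tolist()
    if bad:
        row = bad[0]
        raise DEGTableError(
            f"non-numeric log_fc in row {row + 1} (gene {df.loc[row, 'gene_id']!r})"
        )
    df = df.assign(log_fc=log_fc)

    in_universe = df["gene_id"].isin(universe)
    n_dropped = int((~in_universe).sum())
    if n_dropped:
        logger.warning(
            "read_deg_table: excluded %d gene(s) not in the universe", n_dropped
        )
    df = df[in_universe]

    if adj_p_threshold is not None and "adj_p" in df.columns:
        sig = df[pd.to_numeric(df["adj_p"], errors="coerce") <= adj_p_threshold]
    else:
        sig = df
    delta_e = dict(zip(sig["gene_id"], sig["log_fc"].astype(float)))
    analyzed = frozenset(df["gene_id"])
    return DEGInput(universe=universe, analyzed=analyzed, delta_e=delta_e)


def subpathway_report(subpathways: Sequence) -> pd.DataFrame:
    """Tabulate located subpathways (one row per subpathway)."""
    rows = []
    for i, sp in enumerate(subpathways):
        rows.append(
            {
                "pathway_id": sp.pathway_id,
                "subpathway_index": i,
                "members": ";".join(sorted(sp.members)),
                "n_signature": sp.n_signature,
                "n_total": sp.n_total,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pathway_id", "subpathway_index", "members", "n_signature", "n_total"],
    )


def score_report(scores: Sequence, alpha: float = 0.01) -> pd.DataFrame:
    """Tabulate subpathway scores with a significance flag (fixed column
    order so reports diff cleanly)."""
    rows = []
    for sc in scores:
        rows.append(
            {
                "pathway_id": sc.pathway_id,
                "subpathway_index": sc.subpathway_index,
                "n_genes": sc.n_genes,
                "n_de": sc.n_de,
                "p_nde": sc.p_nde,
                "p_pert": sc.p_pert,
                "p_g": sc.p_g,
                "p_g_fdr": sc.p_g_fdr,
                "significant": sc.p_g_fdr < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "subpathway_index", "n_genes", "n_de",
            "p_nde", "p_pert", "p_g", "p_g_fdr", "significant",
        ],
    )
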