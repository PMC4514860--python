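"""Statistical scoring of subpathways: enrichment, perturbation, combination.

Each located subpathway is scored by two independent pieces of evidence and
their combination, following the impact-analysis framework:

* ``P_NDE`` — upper-tail hypergeometric probability of observing at least
  the seen number of DEGs among the subpathway's genes, given *m* genes in
  the background universe and *n* genes submitted for analysis.
* ``P_PERT`` — a bootstrap p-value for the net accumulated perturbation
  ``t_A``.  Gene perturbation factors satisfy the linear fixed point
  ``PF(g_i) = dE(g_i) + sum_j beta_ij * PF(g_j) / N_ds(g_j)`` over the
  subpathway's directed, signed gene network; ``t_A`` is the total net
  accumulation ``sum_i (PF(g_i) - dE(g_i))``, and its null is built by
  reassigning the observed fold-changes to random genes of the subpathway.
* ``P_G = c - c*ln(c)`` with ``c = P_NDE * P_PERT`` — the exact tail
  probability of the product of two independent uniforms.

Subpathway ``P_G`` values across the whole run form a single
Benjamini-Hochberg family; a pathway is called significant when at least one
of its subpathways survives the FDR threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .kgml_io import DEGInput, GeneGraph
from .locator import Subpathway

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationState",
    "SubpathwayScore",
    "PathwayCall",
    "SingularSystemError",
    "p_nde",
    "perturbation_factors",
    "net_accumulation_weights",
    "p_pert",
    "combine_pg",
    "fdr_adjust",
    "score_subpathways",
    "call_pathways",
]

#: Condition number beyond which (I - B) is treated as numerically singular.
COND_THRESHOLD = 1e12


class SingularSystemError(ValueError):
    """The perturbation system (I - B) is singular or ill-conditioned."""


@dataclass(frozen=True)
class PerturbationState:
    """Solved perturbation factors for one subpathway network."""

    genes: tuple[str, ...]
    pf: dict[str, float]
    acc: dict[str, float]  # net accumulation PF - dE per gene
    t_a: float  # total net accumulation
    beta_matrix: np.ndarray  # B with entries beta_ij / N_ds(g_j)


@dataclass(frozen=True)
class SubpathwayScore:
    pathway_id: str
    subpathway_index: int
    n_genes: int  # t: all members of the trimmed tree
    n_de: int  # r: signature members
    p_nde: float
    p_pert: float
    c: float
    p_g: float
    p_g_fdr: float


@dataclass(frozen=True)
class PathwayCall:
    pathway_id: str
    p: float  # min p_g_fdr over the pathway's subpathways
    n_subpathways: int
    significant: bool


def p_nde(m: int, t: int, n: int, r: int) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    *m* genes in the universe of which *t* lie in the subpathway; *n* genes
    analyzed of which *r* lie in the subpathway.  ``r = 0`` gives 1 (the
    empty sum).
    """
    if not (0 <= t <= m and 0 <= n <= m):
        raise ValueError(f"require 0 <= t, n <= m; got m={m}, t={t}, n={n}")
    if not (0 <= r <= min(t, n)):
        raise ValueError(f"require 0 <= r <= min(t, n); got r={r}, t={t}, n={n}")
    if r == 0:
        return 1.0
    return float(min(1.0, max(0.0, sp_stats.hypergeom.sf(r - 1, m, t, n))))


def _beta_system(graph: GeneGraph) -> tuple[list[str], np.ndarray]:
    """Normalized signed adjacency B with B[i, j] = beta_ij / N_ds(g_j).

    N_ds(g_j) counts the downstream genes of g_j within the subpathway that
    receive a signed (beta != 0) interaction; unsigned edges contribute
    connectivity during location but no perturbation flow.
    """
    genes = sorted(graph.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    b = np.zeros((n, n))
    n_ds = np.zeros(n)
    for s, _t, _rel, beta in graph.edges:
        if beta != 0:
            n_ds[idx[s]] += 1
    for s, t, _rel, beta in graph.edges:
        if beta != 0:
            b[idx[t], idx[s]] += beta / n_ds[idx[s]]
    return genes, b


def perturbation_factors(
    graph: GeneGraph,
    delta_e: Mapping[str, float],
    cond_threshold: float = COND_THRESHOLD,
) -> PerturbationState:
    """Solve the perturbation fixed point (I - B) pf = dE.

    ``delta_e`` should give 0 for non-signature members (missing genes are
    treated as 0).  Raises :class:`SingularSystemError` when (I - B) is
    singular or its condition number exceeds ``cond_threshold``.
    """
    genes, b = _beta_system(graph)
    a = np.eye(len(genes)) - b
    if len(genes) and np.linalg.cond(a) > cond_threshold:
        raise SingularSystemError(
            f"perturbation system ill-conditioned for {graph.pathway_id!r}"
        )
    de = np.array([float(delta_e.get(g, 0.0)) for g in genes])
    pf = np.linalg.solve(a, de) if len(genes) else np.array([])
    acc = pf - de
    return PerturbationState(
        genes=tuple(genes),
        pf=dict(zip(genes, pf.tolist())),
        acc=dict(zip(genes, acc.tolist())),
        t_a=float(acc.sum()),
        beta_matrix=b,
    )


def net_accumulation_weights(
    graph: GeneGraph, cond_threshold: float = COND_THRESHOLD
) -> tuple[list[str], np.ndarray]:
    """Linear functional w with t_A = w . dE.

    Because pf = (I - B)^{-1} dE, the total net accumulation is
    ``1' ((I - B)^{-1} - I) dE``; precomputing w makes the bootstrap null for
    ``t_A`` a cheap vectorized dot product.
    """
    genes, b = _beta_system(graph)
    n = len(genes)
    if n == 0:
        return genes, np.array([])
    a = np.eye(n) - b
    if np.linalg.cond(a) > cond_threshold:
        raise SingularSystemError(
            f"perturbation system ill-conditioned for {graph.pathway_id!r}"
        )
    w = np.linalg.solve(a.T, np.ones(n)) - 1.0
    return genes, w


def p_pert(
    graph: GeneGraph,
    deg: DEGInput,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Bootstrap p-value for the net accumulated perturbation of a subpathway.

    Each of ``n_boot`` draws assigns r fold-changes — sampled without
    replacement from the experiment's full DE value list, so the null stays
    non-degenerate even when every subpathway gene is differential — to r
    genes drawn uniformly without replacement from the subpathway, and
    recomputes ``t_A``.  The two-sided tail probability of the observed
    ``t_A`` against the median-centered null is returned with add-one
    smoothing.  Degenerate cases (no DEGs, no signed edges, singular system)
    return 1.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    members = sorted(graph.nodes)
    sig = [g for g in members if g in deg.delta_e]
    r = len(sig)
    if r == 0:
        return 1.0
    try:
        genes, w = net_accumulation_weights(graph)
    except SingularSystemError:
        logger.warning(
            "p_pert(%s): singular perturbation system; returning 1", graph.pathway_id
        )
        return 1.0
    all_de_vals = np.fromiter(deg.delta_e.values(), dtype=float)
    widx = {g: i for i, g in enumerate(genes)}
    t_obs = float(sum(w[widx[g]] * deg.delta_e[g] for g in sig))

    n = len(genes)
    # r random positions per draw and r random DE values, both without
    # replacement per draw
    pos = np.argsort(rng.random((n_boot, n)), axis=1)[:, :r]
    val_pick = np.argsort(rng.random((n_boot, len(all_de_vals))), axis=1)[:, :r]
    t_null = (w[pos] * all_de_vals[val_pick]).sum(axis=1)

    med = float(np.median(t_null))
    exceed = int(np.sum(np.abs(t_null - med) >= abs(t_obs - med)))
    return (1 + exceed) / (n_boot + 1)


def combine_pg(p_nde_value: float, p_pert_value: float) -> float:
    """Combine enrichment and perturbation evidence: P_G = c - c ln c.

    With c = P_NDE * P_PERT, this is the exact probability that the product
    of two independent uniforms falls at or below c; the c = 0 limit is 0.
    """
    for name, p in (("p_nde", p_nde_value), ("p_pert", p_pert_value)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {p!r}")
    c = p_nde_value * p_pert_value
    if c <= 0.0:
        return 0.0
    if c >= 1.0:
        return 1.0
    return c - c * math.log(c)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    arr = np.asarray(p_values, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def score_subpathways(
    subpathways: Sequence[Subpathway],
    graphs: Mapping[str, GeneGraph],
    deg: DEGInput,
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[SubpathwayScore]:
    """Score every subpathway and BH-adjust P_G across the whole run.

    ``graphs`` maps pathway id to the full pathway gene graph; each
    subpathway is scored on the directed subgraph induced by its members.
    The FDR family is the complete list of subpathways of the run.
    """
    rng = np.random.default_rng(seed)
    partial = []
    index_within: dict[str, int] = {}
    for sp in subpathways:
        idx = index_within.get(sp.pathway_id, 0)
        index_within[sp.pathway_id] = idx + 1
        sub = graphs[sp.pathway_id].induced(sp.members)
        pn = p_nde(m=deg.m, t=sp.n_total, n=deg.n, r=sp.n_signature)
        pp = p_pert(sub, deg, n_boot=n_boot, seed=rng)
        c = pn * pp
        pg = combine_pg(pn, pp)
        partial.append((sp, idx, pn, pp, c, pg))
    if not partial:
        return []
    adj = fdr_adjust([pg for *_rest, pg in partial])
    scores = []
    for (sp, idx, pn, pp, c, pg), pf in zip(partial, adj):
        scores.append(
            SubpathwayScore(
                pathway_id=sp.pathway_id,
                subpathway_index=idx,
                n_genes=sp.n_total,
                n_de=sp.n_signature,
                p_nde=pn,
                p_pert=pp,
                c=c,
                p_g=pg,
                p_g_fdr=pf,
            )
        )
    return scores


def call_pathways(
    scores: Sequence[SubpathwayScore], alpha: float = 0.01
) -> list[PathwayCall]:
    """Roll subpathway scores up to pathway calls.

    A pathway is significant iff its best subpathway has FDR-adjusted
    P_G below ``alpha``; pathways without any located subpathway are absent
    from the output.  Sorted by ascending p.
    """
    by_pathway: dict[str, list[SubpathwayScore]] = {}
    for sc in scores:
        by_pathway.setdefault(sc.pathway_id, []).append(sc)
    calls = [
        PathwayCall(
            pathway_id=pid,
            p=min(sc.p_g_fdr for sc in group),
            n_subpathways=len(group),
            significant=min(sc.p_g_fdr for sc in group) < alpha,
        )
        for pid, group in by_pathway.items()
    ]
    calls.sort(key=lambda c: (c.p, c.pathway_id))
    return calls
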