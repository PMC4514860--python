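# Methods

## Model and procedure

`subspia` treats each signaling pathway as a directed gene-level graph whose
edges carry a signed unit weight β: activation-like relations +1,
inhibition-like −1, everything else (binding, phosphorylation without a
stated sign, indirect effects, …) 0. Unsigned edges still contribute
connectivity — DEG clusters are held together by any interaction — but do
not transmit perturbation. Multi-gene KGML entries (families, complexes) are
expanded to the Cartesian product of gene-level edges;
gene → compound → gene chains are contracted to direct gene–gene edges
carrying the downstream relation's type; parallel edges between an ordered
gene pair collapse to one edge whose β is the clipped sum. These expansion
rules are this package's own reconstruction of KGML semantics — no claim is
made of edge-for-edge equivalence with any other pathway-conversion
library, and the relation→β table is overridable by the caller.

Subpathway location proceeds in three stages (see README for the formulas):
node-set growth controlled by `n_s`, MST extraction over the weighted
undirected subgraph, and trimming of non-signature leaves. Growth is
implemented as the transitive closure of the pairwise admission relation
between signature genes, which makes the outcome provably independent of
the seeding order; the sequential formulation (seed a set with one DEG,
admit reachable DEGs until closure, restart on leftovers) reaches the same
signature partition but an order-dependent set of connectors, so the
closure formulation is the behaviour this package defines. The non-signature
members of a set are the union of the chosen admitting paths over all
qualifying DEG pairs in the component.

Scoring combines an over-representation tail with perturbation evidence.
The hypergeometric P_NDE treats the trimmed tree as the gene set: t counts
all members (connectors included — the conservative direction), r counts
DEGs. The perturbation factors solve the linear fixed point
(I − B)·PF = ΔE, where B[i, j] = β_ij / N_ds(g_j) and N_ds is the number of
signed downstream edges of g_j inside the subpathway-induced subgraph (the
subpathway is the unit of analysis; computing N_ds on the whole pathway is
a one-line change but is not exposed). Non-DEG members have ΔE = 0. The
statistic is the total net accumulation t_A = Σ(PF − ΔE). Because
t_A = 1ᵀ((I − B)⁻¹ − I)·ΔE is linear in ΔE, the bootstrap null is computed
as a vectorized dot product of precomputed weights with resampled ΔE
vectors; a unit test pins this to the explicit per-draw solve.

### Bootstrap null for P_PERT

Each draw assigns r fold-changes to r genes sampled uniformly without
replacement from the subpathway; the values are sampled without replacement
from the experiment's full DE value list, not merely the subpathway's own
values. The narrower within-subpathway shuffle degenerates whenever every
subpathway gene is a DEG (the null then reproduces the observed t_A
exactly, forcing p = 1 even for a maximally coherent cascade); drawing from
the full DE list keeps the null informative in exactly the situation the
method is built to detect. The p-value is the two-sided tail of the
observed t_A against the median-centered null with add-one smoothing,
(1 + #{|t_null − med| ≥ |t_obs − med|}) / (n_boot + 1), so it is never 0
and is uniform under a symmetric null. Subpathways with no DEGs, no signed
edges, or a numerically singular (I − B) (condition number above 10¹²,
e.g. a two-gene feedback loop of lone activations with unit gain) receive
p = 1 with a logged warning rather than an error.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_s` | 4 | max non-signature genes on an admitting shortest path; smaller values yield smaller, purer subpathways |
| `distance_rule` | `intermediates` | whether `n_s` bounds the count of non-signature intermediates or the path length in edges (`edges`: ≤ n_s + 1); the readings differ when DEGs lie on the path |
| `alpha` | 0.01 | FDR threshold on BH-adjusted P_G; the BH family is all subpathways of the run |
| `n_boot` | 2000 | perturbation bootstrap draws |
| `n_perm` | 10000 | random subsets for the topology degree p-value |
| `k_zero_penalty` | 2.0 | stands in for 1/k when a non-signature node has no signature neighbour (possible once `n_s` ≥ 3); any value > 1 keeps such nodes strictly costlier than any k ≥ 1 node |
| `min_signature_nodes` | 1 | singleton DEGs are located and scored by default; raise to suppress them |

Kruskal ties are broken by sorting edges on (weight, min endpoint, max
endpoint); admitting-path ties by the lexicographically smallest node
sequence among qualifying minimum-length paths. Both choices exist purely
for determinism.

## Topology analysis

The pathway-level network links two pathways when either KGML document
cross-references the other (map entries / maplink relations); a
shared-genes rule (edge iff ≥ k common genes) is available for sensitivity
checks and is recorded in the output metadata. Degree and unnormalized
shortest-path betweenness are whole-network quantities averaged over the
subset; clustering is the Watts–Strogatz local coefficient of subset nodes
within the subgraph induced by the subset plus its direct neighbours
(with all neighbours present this equals the whole-network local
coefficient; the neighbour-inclusive subgraph is what the reported subset
is drawn from). The degree p-value is the add-one-smoothed fraction of
uniformly random same-size subsets whose mean degree reaches the observed
mean.

## Synthetic data

The generator emulates what the method assumes about real pathways: sparse
directed graphs dominated by linear cascades (a chain backbone over a
random gene permutation plus uniform shortcuts to the target density,
default 0.05 of possible directed edges), mostly signed regulation (90%
signed, 70/30 activation/inhibition), and DEGs concentrated in a connected
local region (a random-walk-grown module of 6 genes at |ΔE| = 3 with
N(0, 0.3) noise and one coherent sign, over background DEGs at 2% per gene
with N(0, 1) fold-changes). `simulate_cohort` gives several such pathways
disjoint gene namespaces, plants the module in the first, and pools the
universe, so the remaining pathways act as decoys under a shared DEG list.

What passing tests on these fixtures do **not** show: robustness to the
identifier mapping, normalization and DEG-calling steps of a real
microarray or RNA-seq analysis (the DEG table is an input here); realistic
correlation between expression changes of neighbouring genes beyond the
planted module; or the exact topology statistics of any historical KEGG
snapshot.

## Numerical choices and degenerate inputs

Hypergeometric tails come from `scipy.stats.hypergeom.sf` (clamped to
[0, 1]); the acceptance suite pins them to exact rational enumeration over
every valid configuration with m ≤ 20 at 1e-12. The linear solves use
dense LAPACK; subpathways are small (tens of genes), so conditioning is
checked directly via the condition number. P_G uses the closed form
c − c·ln(c) with the c = 0 limit defined as 0. Empty signature → no node
sets (not an error); signature genes absent from a pathway are skipped with
a log message; a DEG table row outside the universe is excluded with a
warning, while duplicate genes and non-numeric fold-changes are errors.

## Known limitations

- **The subpathway P_G is not calibrated under a global null.** The
  enrichment term is computed for a region *selected* for DEG density, so a
  chance cluster of two or more linked DEGs already yields a small
  hypergeometric tail; simulations in the acceptance suite measure roughly
  40–60% of null subpathways at P_G < 0.05 depending on the DEG rate. This
  selection effect is intrinsic to scoring located subpathways (a fixed
  whole-pathway gene set does not have it) and is the price of the method's
  resolution; p-values should be read as a ranking strengthened by FDR
  control, not as frequentist error rates. The planted/decoy simulations
  show the practical consequence is mild at FDR 1% (decoy pathways called
  in ≈ 4–6% of trials), but the nominal level is not guaranteed.
- Growth admits connectors only along minimum-edge-count shortest paths; a
  longer path with fewer non-signature genes is never considered.
- Compound contraction keeps the downstream relation's sign only; chains of
  two inhibitions through a compound are not multiplied through.
- The pathway–pathway edge rule of any given KEGG release (map entries
  vs maplink relations vs shared genes) affects topology statistics; both
  implemented rules are labelled in the output.
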