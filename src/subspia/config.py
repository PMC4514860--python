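"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    """Tunable parameters of a sub-SPIA run.

    n_s            maximum non-signature nodes permitted on an admitting
                   shortest path during node-set growth (default 4).
    alpha          FDR threshold on adjusted P_G for significance (default 1%).
    n_boot         bootstrap draws for the perturbation null (default 2000).
    n_perm         random subsets for the topology degree p-value (default 10000).
    seed           master seed for all stochastic stages.
    universe_mode  which background the hypergeometric m refers to:
                   "platform" (the supplied universe) or "genome".
    distance_rule  growth admission rule: "intermediates" (count of
                   non-signature intermediates <= n_s) or "edges" (path
                   length <= n_s + 1 edges).
    pathway_edge_rule  pathway-network construction: "maplink" cross
                   references or "shared_genes".
    k_zero_penalty  finite stand-in for 1/k when a non-signature node has no
                   signature neighbour in the weighted subgraph.
    min_signature_nodes  smallest signature count for a reported subpathway.
    """

    n_s: int = 4
    alpha: float = 0.01
    n_boot: int = 2000
    n_perm: int = 10_000
    seed: int = 0
    universe_mode: str = "platform"
    distance_rule: str = "intermediates"
    pathway_edge_rule: str = "maplink"
    k_zero_penalty: float = 2.0
    min_signature_nodes: int = 1

    def __post_init__(self) -> None:
        if self.n_s < 0:
            raise ValueError("n_s must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.universe_mode not in ("platform", "genome"):
            raise ValueError("universe_mode must be 'platform' or 'genome'")
        if self.distance_rule not in ("intermediates", "edges"):
            raise ValueError("distance_rule must be 'intermediates' or 'edges'")
        if self.pathway_edge_rule not in ("maplink", "shared_genes"):
            raise ValueError("pathway_edge_rule must be 'maplink' or 'shared_genes'")

    def to_text(self) -> str:
        """Flat ``key = value`` serialization (lossless round-trip)."""
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        kwargs = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)
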