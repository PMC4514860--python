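"""Unit tests for enrichment, perturbation and p-value combination."""

from __future__ import annotations

import itertools
import math
import shutil
import subprocess
from fractions import Fraction

import numpy as np
import pytest

from subspia.kgml_io import DEGInput
from subspia.spia_stats import (
    SingularSystemError,
    call_pathways,
    combine_pg,
    fdr_adjust,
    net_accumulation_weights,
    p_nde,
    p_pert,
    perturbation_factors,
    score_subpathways,
    SubpathwayScore,
)
from subspia.synthetic_data import generate_pathway

from conftest import make_graph


def hypergeom_tail_exact(m, t, n, r):
    """Exact upper-tail P(X >= r) via rational arithmetic (oracle)."""
    total = math.comb(m, n)
    return float(
        sum(Fraction(math.comb(t, x) * math.comb(m - t, n - x), total)
            for x in range(r, min(t, n) + 1))
    )


class TestPNDE:
    def test_r_zero_is_one(self):
        assert p_nde(10, 4, 5, 0) == 1.0

    def test_small_case_by_draw_enumeration(self):
        # m=10, t=4, n=5, r=4: enumerate all C(10,5) draws
        pathway = set(range(4))
        hits = sum(
            1 for draw in itertools.combinations(range(10), 5)
            if len(pathway & set(draw)) >= 4
        )
        expected = hits / math.comb(10, 5)
        assert expected == pytest.approx(6 / 252)
        assert p_nde(10, 4, 5, 4) == pytest.approx(expected, abs=1e-12)

    def test_medium_case_by_draw_enumeration(self):
        pathway = set(range(5))
        hits = sum(
            1 for draw in itertools.combinations(range(20), 6)
            if len(pathway & set(draw)) >= 3
        )
        assert p_nde(20, 5, 6, 3) == pytest.approx(hits / math.comb(20, 6), abs=1e-12)

    def test_exact_oracle_spot_checks(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 21))
            t = int(rng.integers(0, m + 1))
            n = int(rng.integers(0, m + 1))
            r = int(rng.integers(0, min(t, n) + 1))
            assert p_nde(m, t, n, r) == pytest.approx(
                hypergeom_tail_exact(m, t, n, r), abs=1e-12
            )

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            p_nde(10, 11, 5, 2)
        with pytest.raises(ValueError):
            p_nde(10, 4, 5, 5)


class TestPerturbationFactors:
    def test_isolated_gene(self):
        g = make_graph([], nodes=["a"])
        state = perturbation_factors(g, {"a": 2.0})
        assert state.pf["a"] == pytest.approx(2.0)
        assert state.acc["a"] == pytest.approx(0.0)
        assert state.t_a == pytest.approx(0.0)

    def test_activating_chain_propagates(self):
        g = make_graph([("g1", "g2", "activation")])
        state = perturbation_factors(g, {"g1": 1.0, "g2": 0.0})
        assert state.pf["g2"] == pytest.approx(1.0)
        assert state.acc["g2"] == pytest.approx(1.0)
        assert state.t_a == pytest.approx(1.0)

    def test_inhibiting_chain_flips_sign(self):
        g = make_graph([("g1", "g2", "inhibition")])
        state = perturbation_factors(g, {"g1": 1.0})
        assert state.pf["g2"] == pytest.approx(-1.0)
        assert state.t_a == pytest.approx(-1.0)

    def test_fanout_normalized_by_downstream_count(self):
        # g1 activates g2 and g3: each receives PF(g1)/2
        g = make_graph([("g1", "g2", "activation"), ("g1", "g3", "activation")])
        state = perturbation_factors(g, {"g1": 2.0})
        assert state.pf["g2"] == pytest.approx(1.0)
        assert state.pf["g3"] == pytest.approx(1.0)

    def test_unsigned_edges_carry_no_flow(self):
        g = make_graph([("g1", "g2", "binding/association")])
        state = perturbation_factors(g, {"g1": 5.0})
        assert state.pf["g2"] == pytest.approx(0.0)

    def test_two_cycle_with_unit_gain_is_singular(self):
        g = make_graph([("a", "b", "activation"), ("b", "a", "activation")])
        with pytest.raises(SingularSystemError):
            perturbation_factors(g, {"a": 1.0})

    def test_residual_on_random_solvable_graphs(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 40:
            graph = generate_pathway(
                int(rng.integers(5, 30)), edge_density=0.08,
                seed=int(rng.integers(2**31)),
            )
            de = {g: float(rng.normal()) for g in sorted(graph.nodes)[:5]}
            try:
                state = perturbation_factors(graph, de)
            except SingularSystemError:
                continue
            genes = list(state.genes)
            pf = np.array([state.pf[g] for g in genes])
            dev = np.array([de.get(g, 0.0) for g in genes])
            resid = pf - dev - state.beta_matrix @ pf
            assert np.max(np.abs(resid)) <= 1e-9
            checked += 1

    def test_weights_reproduce_t_a(self):
        rng = np.random.default_rng(12)
        graph = generate_pathway(15, edge_density=0.1, seed=3)
        de = {g: float(rng.normal()) for g in sorted(graph.nodes)[:4]}
        state = perturbation_factors(graph, de)
        genes, w = net_accumulation_weights(graph)
        t_a = sum(w[i] * de.get(g, 0.0) for i, g in enumerate(genes))
        assert t_a == pytest.approx(state.t_a, abs=1e-9)


class TestPPert:
    def _deg(self, graph, delta_e):
        return DEGInput(
            universe=graph.nodes, analyzed=frozenset(delta_e), delta_e=delta_e
        )

    def test_no_edges_gives_one(self):
        g = make_graph([], nodes=["a", "b", "c"])
        deg = self._deg(g, {"a": 3.0})
        assert p_pert(g, deg, n_boot=200, seed=0) == 1.0

    def test_no_degs_gives_one(self):
        g = make_graph([("a", "b", "activation")])
        deg = DEGInput(universe=g.nodes, analyzed=frozenset())
        assert p_pert(g, deg, n_boot=200, seed=0) == 1.0

    def test_reproducible_given_seed(self):
        g = generate_pathway(20, edge_density=0.1, seed=5)
        de = {gene: 2.0 for gene in sorted(g.nodes)[:4]}
        deg = self._deg(g, de)
        assert p_pert(g, deg, n_boot=500, seed=7) == p_pert(g, deg, n_boot=500, seed=7)

    def test_coherent_chain_perturbation_is_significant(self):
        """All ΔE = +3 along an activating chain of 6 accumulates far beyond
        a null that redraws DE values from the experiment's full DE list."""
        chain = [(f"c{i}", f"c{i+1}", "activation") for i in range(5)]
        g = make_graph(chain)
        de = {f"c{i}": 3.0 for i in range(6)}
        rng = np.random.default_rng(0)
        de.update({f"bg{i}": float(rng.normal()) for i in range(12)})
        universe = g.nodes | {f"bg{i}" for i in range(12)}
        deg = DEGInput(universe=universe, analyzed=frozenset(de), delta_e=de)
        assert p_pert(g, deg, n_boot=2000, seed=1) <= 0.05

    def test_singular_system_returns_one(self):
        g = make_graph([("a", "b", "activation"), ("b", "a", "activation")])
        deg = self._deg(g, {"a": 1.0})
        assert p_pert(g, deg, n_boot=200, seed=0) == 1.0

    def test_roughly_uniform_under_null(self):
        """Random ΔE placement should give an approximately uniform p-value
        (coarse KS check; the acceptance suite runs the calibrated one)."""
        from scipy import stats as sp_stats

        g = generate_pathway(20, edge_density=0.12, seed=9)
        nodes = sorted(g.nodes)
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(150):
            chosen = rng.choice(nodes, size=5, replace=False)
            de = {gene: float(rng.normal()) for gene in chosen}
            deg = self._deg(g, de)
            pvals.append(p_pert(g, deg, n_boot=400, seed=rng))
        assert sp_stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCombinePG:
    def test_limits(self):
        assert combine_pg(1.0, 1.0) == 1.0
        assert combine_pg(0.0, 0.5) == 0.0

    def test_closed_form_value(self):
        c = 1e-4
        assert combine_pg(0.01, 0.01) == pytest.approx(c - c * math.log(c))
        assert combine_pg(0.01, 0.01) == pytest.approx(1.0210e-3, rel=1e-3)

    def test_matches_monte_carlo_product_tail(self):
        rng = np.random.default_rng(123)
        u = rng.random((100_000, 2))
        prod = u[:, 0] * u[:, 1]
        for c in (1e-2, 0.1, 0.5):
            mc = float(np.mean(prod <= c))
            se = math.sqrt(mc * (1 - mc) / len(prod))
            assert abs(combine_pg(c, 1.0) - mc) <= 3 * se

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            combine_pg(-0.1, 0.5)
        with pytest.raises(ValueError):
            combine_pg(0.5, 1.5)


class TestFDR:
    def test_hand_worked_example(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert fdr_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_permutation_equivariant(self):
        p = [0.001, 0.2, 0.04, 0.9, 0.04]
        adj = fdr_adjust(p)
        perm = [4, 2, 0, 1, 3]
        adj_perm = fdr_adjust([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(6)
        p = rng.random(20).tolist()
        adj = fdr_adjust(p)
        assert all(0 <= a <= 1 and a >= raw - 1e-12 for a, raw in zip(adj, p))

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_r_p_adjust(self):
        """Independent oracle: R's p.adjust(method='BH')."""
        p = [0.003, 0.04, 0.2, 0.04, 0.9, 0.0007]
        script = (
            'cat(p.adjust(c(' + ",".join(map(str, p)) + '), method="BH"), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = [float(x) for x in out.stdout.split()]
        assert fdr_adjust(p) == pytest.approx(expected, rel=1e-10)


class TestCallPathways:
    def _score(self, pid, idx, p_fdr):
        return SubpathwayScore(
            pathway_id=pid, subpathway_index=idx, n_genes=5, n_de=3,
            p_nde=0.1, p_pert=0.1, c=0.01, p_g=p_fdr, p_g_fdr=p_fdr,
        )

    def test_threshold_rule(self):
        calls = call_pathways(
            [self._score("pw1", 0, 0.005), self._score("pw2", 0, 0.02)], alpha=0.01
        )
        by_id = {c.pathway_id: c for c in calls}
        assert by_id["pw1"].significant and not by_id["pw2"].significant

    def test_pathway_without_subpathway_absent(self):
        calls = call_pathways([self._score("pw1", 0, 0.005)])
        assert [c.pathway_id for c in calls] == ["pw1"]

    def test_min_over_subpathways_and_sorting(self):
        calls = call_pathways(
            [
                self._score("pw1", 0, 0.4),
                self._score("pw1", 1, 0.002),
                self._score("pw2", 0, 0.0001),
            ],
            alpha=0.01,
        )
        assert [c.pathway_id for c in calls] == ["pw2", "pw1"]
        assert calls[1].p == pytest.approx(0.002)
        assert calls[1].n_subpathways == 2


class TestScoreSubpathways:
    def test_end_to_end_scoring_fields_consistent(self):
        from subspia.locator import locate_subpathways
        from subspia.synthetic_data import plant_de_module

        graph = generate_pathway(40, edge_density=0.05, seed=21)
        deg, _truth = plant_de_module(graph, module_size=5, seed=21)
        sps = locate_subpathways(graph, deg)
        scores = score_subpathways(sps, {graph.pathway_id: graph}, deg, n_boot=200, seed=0)
        assert len(scores) == len(sps)
        for sc in scores:
            assert 0 <= sc.p_nde <= 1 and 0 <= sc.p_pert <= 1
            assert sc.c == pytest.approx(sc.p_nde * sc.p_pert)
            assert sc.p_g_fdr >= sc.p_g - 1e-12
            assert sc.p_g == pytest.approx(combine_pg(sc.p_nde, sc.p_pert))

    def test_deterministic_given_seed(self):
        from subspia.locator import locate_subpathways
        from subspia.synthetic_data import plant_de_module

        graph = generate_pathway(30, edge_density=0.06, seed=22)
        deg, _ = plant_de_module(graph, module_size=4, seed=22)
        sps = locate_subpathways(graph, deg)
        a = score_subpathways(sps, {graph.pathway_id: graph}, deg, n_boot=300, seed=5)
        b = score_subpathways(sps, {graph.pathway_id: graph}, deg, n_boot=300, seed=5)
        assert a == b
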