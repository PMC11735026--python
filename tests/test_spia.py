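"""Customized SPIA: perturbation propagation, evidence p-values, combination."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromloop_v2g.spia import (
    PathwayGraph,
    centrality_evidence,
    combine_and_adjust,
    gene_importance_scores,
    p_ora,
    p_pert,
    perturbation,
    run_spia,
    stouffer_combine,
)
from chromloop_v2g.synthetic import chain_pathway, planted_chain_scenario


def random_dag(rng, n_nodes):
    genes = tuple(f"n{i}" for i in range(n_nodes))
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < 0.4:
                edges.append((genes[i], genes[j], float(rng.choice([1.0, -1.0]))))
    return PathwayGraph("dag", genes, tuple(edges))


def iterative_propagation_oracle(pathway, delta_e, n_iter=500):
    """Fixed-point iteration of PF(g) = dE(g) + sum_j beta_jg PF(j)/N_ds(j)."""
    genes = list(pathway.genes)
    out_deg = {g: 0 for g in genes}
    for s, _, _ in pathway.edges:
        out_deg[s] += 1
    pf = {g: float(delta_e.get(g, 0.0)) for g in genes}
    for _ in range(n_iter):
        new = {}
        for g in genes:
            acc = float(delta_e.get(g, 0.0))
            for s, t, w in pathway.edges:
                if t == g:
                    acc += w * pf[s] / out_deg[s]
            new[g] = acc
        pf = new
    return pf


class TestPerturbation:
    def test_zero_de_gives_zero_everywhere(self):
        pw = chain_pathway(4)
        res = perturbation(pw, {})
        assert (res.pf == 0).all() and res.ta == 0.0

    def test_two_gene_chain_closed_form(self):
        pw = PathwayGraph("c", ("A", "B"), (("A", "B", 1.0),))
        res = perturbation(pw, {"A": 2.0})
        assert res.pf.tolist() == [2.0, 2.0]
        assert res.acc["B"] == 2.0 and res.acc["A"] == 0.0
        assert res.ta == 2.0

    def test_matches_fixed_point_oracle_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            pw = random_dag(rng, int(rng.integers(2, 9)))
            de = {g: float(rng.normal()) for g in pw.genes}
            res = perturbation(pw, de)
            oracle = iterative_propagation_oracle(pw, de)
            for g in pw.genes:
                assert res.pf[g] == pytest.approx(oracle[g], abs=1e-9)

    def test_linearity_in_de(self):
        rng = np.random.default_rng(1)
        pw = random_dag(rng, 6)
        de = {g: float(rng.normal()) for g in pw.genes}
        ta1 = perturbation(pw, de).ta
        ta2 = perturbation(pw, {g: 2 * v for g, v in de.items()}).ta
        assert ta2 == pytest.approx(2 * ta1, rel=1e-12)

    def test_unit_eigenvalue_cycle_damped_and_flagged(self):
        pw = PathwayGraph("cyc", ("A", "B"), (("A", "B", 1.0), ("B", "A", 1.0)))
        res = perturbation(pw, {"A": 1.0})
        assert res.damped
        assert np.isfinite(res.pf).all()


class TestPPert:
    def test_all_zero_de_is_one(self):
        assert p_pert(chain_pathway(5), {}, n_boot=200, rng=0) == 1.0

    def test_planted_chain_perturbation_detected(self):
        chain, delta, de_set, universe = planted_chain_scenario(seed=3)
        masked = {g: (delta[g] if g in set(de_set) else 0.0) for g in universe}
        assert p_pert(chain, masked, n_boot=2000, rng=0) <= 0.01

    def test_null_p_values_roughly_uniform(self):
        # KS test of p_pert under a null dE over repeated datasets
        rng = np.random.default_rng(7)
        chain = chain_pathway(6)
        universe = [f"g{i}" for i in range(100)] + list(chain.genes)
        ps = []
        for _ in range(300):
            de = {g: float(rng.normal()) for g in universe}
            ps.append(p_pert(chain, de, n_boot=200, rng=rng))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_seeded_reproducibility(self):
        chain, delta, de_set, universe = planted_chain_scenario(seed=1)
        masked = {g: (delta[g] if g in set(de_set) else 0.0) for g in universe}
        assert p_pert(chain, masked, rng=5) == p_pert(chain, masked, rng=5)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            p_pert(chain_pathway(3), {"chain_g0": 1.0}, n_boot=10, rng=0)


class TestPOra:
    def test_zero_overlap_is_one(self):
        pw = PathwayGraph("p", ("a", "b"))
        assert p_ora(pw, de_set=["x"], universe=["a", "b", "x", "y"]) == 1.0

    def test_full_overlap_exact_combinatorics(self):
        universe = [f"u{i}" for i in range(20)]
        pw = PathwayGraph("p", tuple(universe[:10]))
        p = p_ora(pw, de_set=universe[:10], universe=universe)
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-12)

    def test_matches_enumeration_oracle(self):
        universe = [f"u{i}" for i in range(15)]
        pw = PathwayGraph("p", tuple(universe[:6]))
        de = universe[3:10]  # overlap k = 3
        p = p_ora(pw, de, universe)
        # enumeration: P(X >= 3), X hypergeometric(N=15, K=6, n=7)
        expected = sum(
            math.comb(6, k) * math.comb(9, 7 - k) / math.comb(15, 7) for k in range(3, 7)
        )
        assert p == pytest.approx(expected, rel=1e-12)


class TestCentralityEvidence:
    def _pathway_pair(self):
        hub = "hub"
        leaves = tuple(f"leaf{i}" for i in range(6))
        edges = tuple((hub, l, 1.0) for l in leaves) + tuple((l, hub, 1.0) for l in leaves)
        star = PathwayGraph("star", (hub,) + leaves, edges)
        other = chain_pathway(4, pathway_id="other")
        return star, other

    def test_empty_de_set_all_one(self):
        star, other = self._pathway_pair()
        res = centrality_evidence([star, other], [], list(star.genes) + list(other.genes),
                                  n_boot=200, rng=0)
        assert (res[["p_impact", "p_neighborhood", "p_betweenness", "p_enrichment"]] == 1).all().all()

    def test_gene_in_all_pathways_has_impact_one(self):
        shared = "shared"
        p1 = PathwayGraph("a", (shared, "x"))
        p2 = PathwayGraph("b", (shared, "y"))
        scores = gene_importance_scores([p1, p2])
        assert scores["a"].loc[shared, "impact"] == 1.0
        assert scores["b"].loc[shared, "impact"] == 1.0

    def test_hub_in_de_set_beats_leaf_on_betweenness(self):
        star, other = self._pathway_pair()
        universe = list(star.genes) + list(other.genes) + [f"bg{i}" for i in range(50)]
        p_hub = centrality_evidence([star, other], ["hub"], universe, n_boot=2000, rng=0)
        p_leaf = centrality_evidence([star, other], ["leaf0"], universe, n_boot=2000, rng=0)
        hub_p = p_hub.set_index("pathway_id").loc["star", "p_betweenness"]
        leaf_p = p_leaf.set_index("pathway_id").loc["star", "p_betweenness"]
        assert hub_p < leaf_p

    def test_betweenness_agrees_with_networkx(self):
        star, other = self._pathway_pair()
        scores = gene_importance_scores([star, other])
        nx_b = nx.betweenness_centrality(star.to_networkx(), normalized=True)
        for g in star.genes:
            assert scores["star"].loc[g, "betweenness"] == pytest.approx(nx_b[g])

    def test_needs_two_pathways(self):
        with pytest.raises(ValueError, match="2 pathways"):
            centrality_evidence([chain_pathway(3)], [], ["a"], rng=0)


class TestCombineAndAdjust:
    def test_stouffer_symmetry_at_half(self):
        assert stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_stouffer_against_high_precision_oracle(self):
        import mpmath

        mpmath.mp.dps = 40
        z = 2 * mpmath.erfinv(2 * mpmath.mpf("0.95") - 1) * mpmath.sqrt(2) / mpmath.sqrt(2)
        # z = 2 * Phi^-1(0.95) / sqrt(2); p = 1 - Phi(z)
        phi_inv_95 = mpmath.sqrt(2) * mpmath.erfinv(2 * mpmath.mpf("0.95") - 1)
        zz = 2 * phi_inv_95 / mpmath.sqrt(2)
        expected = float(mpmath.mpf(1) / 2 * mpmath.erfc(zz / mpmath.sqrt(2)))
        assert stouffer_combine([0.05, 0.05]) == pytest.approx(expected, rel=1e-10)

    def test_single_pathway_bonferroni_equals_fdr_equals_combined(self):
        df = pd.DataFrame([{"pathway_id": "p", "p_pert": 0.03, "p_enrichment": 0.2}])
        out = combine_and_adjust(df)
        assert out.loc[0, "p_bonferroni"] == pytest.approx(out.loc[0, "p_combined"])
        assert out.loc[0, "p_fdr"] == pytest.approx(out.loc[0, "p_combined"])

    def test_bh_below_bonferroni_pointwise(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "pathway_id": [f"p{i}" for i in range(20)],
                "p_pert": rng.uniform(0, 1, 20),
                "p_enrichment": rng.uniform(0, 1, 20),
            }
        )
        out = combine_and_adjust(df)
        assert (out["p_fdr"] <= out["p_bonferroni"] + 1e-12).all()

    def test_missing_evidence_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            combine_and_adjust(pd.DataFrame({"pathway_id": ["p"], "p_pert": [0.5]}))


class TestRunSpia:
    def test_reports_all_evidence_columns(self):
        chain, delta, de_set, universe = planted_chain_scenario(seed=0)
        other = chain_pathway(4, pathway_id="filler")
        res = run_spia([chain, other], delta, de_set, list(universe) + list(other.genes),
                       n_boot=200, seed=1)
        for col in ("ta", "p_pert", "p_ora", "p_impact", "p_neighborhood",
                    "p_betweenness", "p_enrichment", "p_combined", "p_bonferroni", "p_fdr"):
            assert col in res.columns
        assert res[[c for c in res.columns if c.startswith("p_")]].le(1).all().all()

    def test_seeded_reproducibility(self):
        chain, delta, de_set, universe = planted_chain_scenario(seed=0)
        other = chain_pathway(4, pathway_id="filler")
        uni = list(universe) + list(other.genes)
        r1 = run_spia([chain, other], delta, de_set, uni, n_boot=200, seed=42)
        r2 = run_spia([chain, other], delta, de_set, uni, n_boot=200, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_de_gene_outside_universe_rejected(self):
        chain = chain_pathway(3)
        with pytest.raises(ValueError, match="absent"):
            run_spia([chain, chain_pathway(3, "b")], {"ghost": 1.0}, [], list(chain.genes),
                     n_boot=200, seed=0)
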