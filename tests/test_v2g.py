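"""Proxy Venn classification, gene implication, summaries, expression scaling."""

import numpy as np
import pandas as pd
import pytest

from chromloop_v2g.cre import call_cres
from chromloop_v2g.intervals import GenomicInterval, LoopCall, Peak, PromoterWindow
from chromloop_v2g.v2g import (
    CellTypeAssets,
    classify_proxies,
    load_proxies,
    map_variants_to_genes,
    scale_expression,
    summarize,
)


def proxy_table(rows):
    return pd.DataFrame(
        rows, columns=["rsid", "chrom", "pos", "sentinel_rsid", "r2", "locus_id"]
    )


def make_assets(cell_type, peaks=(), loops=(), promoters=()):
    peaks = tuple(Peak(GenomicInterval("chr1", s, e), cell_type) for s, e in peaks)
    loops = tuple(
        LoopCall(GenomicInterval("chr1", *a), GenomicInterval("chr1", *b), cell_type)
        for a, b in loops
    )
    proms = tuple(
        PromoterWindow(g, GenomicInterval("chr1", s, e), "+", s + 1500)
        for g, s, e in promoters
    )
    cres = tuple(call_cres(list(peaks), list(loops), list(proms), cell_type))
    return CellTypeAssets(cell_type, peaks, loops, cres)


class TestLoadProxies:
    def test_r2_filter_applied(self):
        df = proxy_table(
            [("rs1", "chr1", 10, "s", 0.95, "L0"), ("rs2", "chr1", 20, "s", 0.5, "L0")]
        )
        out = load_proxies(df)
        assert list(out["rsid"]) == ["rs1"]

    def test_position_must_be_one_based(self):
        df = proxy_table([("rs1", "chr1", 0, "s", 0.9, "L0")])
        with pytest.raises(ValueError, match="1-based"):
            load_proxies(df)


class TestClassifyProxies:
    def test_closed_anchor_gives_contact_only(self):
        assets = make_assets("CT", loops=[((100, 2000), (50_000, 52_000))])
        out = classify_proxies(proxy_table([("rs1", "chr1", 1000, "s", 0.9, "L0")]), [assets])
        assert out.loc[0, "stratum"] == "contact_only"

    def test_cre_takes_precedence(self):
        # peak overlapping an anchor of a promoter-connected loop -> cre
        assets = make_assets(
            "CT",
            peaks=[(900, 1200)],
            loops=[((800, 2000), (50_000, 52_000))],
            promoters=[("G1", 50_500, 52_500)],
        )
        assert len(assets.cres) == 1
        out = classify_proxies(proxy_table([("rs1", "chr1", 1000, "s", 0.9, "L0")]), [assets])
        assert out.loc[0, "stratum"] == "cre"
        assert out.loc[0, "in_open"] and out.loc[0, "in_contact"]

    def test_open_contact_requires_same_cell_type(self):
        open_ct = make_assets("A", peaks=[(900, 1200)])
        contact_ct = make_assets("B", loops=[((800, 2000), (50_000, 52_000))])
        out = classify_proxies(
            proxy_table([("rs1", "chr1", 1000, "s", 0.9, "L0")]), [open_ct, contact_ct]
        )
        # open and contact co-occur only across cell types: contact wins
        assert out.loc[0, "stratum"] == "contact_only"
        out2 = classify_proxies(
            proxy_table([("rs1", "chr1", 1000, "s", 0.9, "L0")]),
            [make_assets("A", peaks=[(900, 1200)], loops=[((800, 2000), (50_000, 52_000))])],
        )
        assert out2.loc[0, "stratum"] == "open_contact"

    def test_strata_partition_proxy_set(self, default_dataset):
        ds = default_dataset
        out = classify_proxies(load_proxies(ds.proxies), ds.assets)
        assert len(out) == len(ds.proxies)
        assert out["stratum"].isin(
            ["cre", "open_contact", "contact_only", "open_only", "none"]
        ).all()
        counts = out["stratum"].value_counts()
        assert counts.sum() == len(ds.proxies)

    def test_strata_match_planted_truth(self, default_dataset):
        ds = default_dataset
        out = classify_proxies(load_proxies(ds.proxies), ds.assets)
        merged = out[["rsid", "stratum"]].merge(
            ds.truth.strata, on="rsid", suffixes=("_obs", "_true")
        )
        assert (merged["stratum_obs"] == merged["stratum_true"]).all()

    def test_unknown_chromosome_warns_and_yields_none(self):
        assets = make_assets("CT", peaks=[(900, 1200)])
        with pytest.warns(UserWarning, match="absent"):
            out = classify_proxies(
                proxy_table([("rs1", "chrX", 1000, "s", 0.9, "L0")]), [assets]
            )
        assert out.loc[0, "stratum"] == "none"


class TestMapVariantsToGenes:
    def test_distal_cre_yields_loop_mechanism(self):
        assets = make_assets(
            "CT",
            peaks=[(900, 1200)],
            loops=[((800, 2000), (50_000, 52_000))],
            promoters=[("G1", 50_500, 52_500)],
        )
        rec = map_variants_to_genes(
            proxy_table([("rs1", "chr1", 1000, "s", 0.9, "L0")]), [assets]
        )
        assert len(rec) == 1
        assert rec.loc[0, "gene_id"] == "G1" and rec.loc[0, "mechanism"] == "loop"

    def test_promoter_and_loop_evidence_collapse_to_double(self):
        # peak inside G1's promoter AND distal peak looping to G1, same variant
        assets = make_assets(
            "CT",
            peaks=[(50_600, 52_400), (900, 1200)],
            loops=[((800, 2000), (50_000, 52_000))],
            promoters=[("G1", 50_500, 52_500)],
        )
        proxies = proxy_table(
            [("rs1", "chr1", 1000, "s", 0.9, "L0"), ("rs1", "chr1", 51_000, "s", 0.9, "L0")]
        )
        rec = map_variants_to_genes(proxies, [assets])
        assert len(rec) == 1
        assert rec.loc[0, "mechanism"] == "double"

    def test_no_cre_resident_proxy_empty(self):
        assets = make_assets("CT", peaks=[(900, 1200)])
        rec = map_variants_to_genes(
            proxy_table([("rs1", "chr1", 5_000, "s", 0.9, "L0")]), [assets]
        )
        assert rec.empty

    def test_planted_truth_recovered_exactly(self, default_dataset):
        ds = default_dataset
        rec = map_variants_to_genes(load_proxies(ds.proxies), ds.assets)
        obs = set(map(tuple, rec[["rsid", "gene_id", "cell_type"]].itertuples(index=False)))
        true = set(
            map(tuple, ds.truth.links[["rsid", "gene_id", "cell_type"]].itertuples(index=False))
        )
        assert obs == true

    def test_undetected_expression_flagged(self):
        assets = make_assets("CT", peaks=[(50_600, 50_900)], promoters=[("G1", 50_500, 52_500)])
        expr = scale_expression(pd.DataFrame({"CT": [1.0]}, index=["other_gene"]))
        rec = map_variants_to_genes(
            proxy_table([("rs1", "chr1", 50_700, "s", 0.9, "L0")]), [assets], expression=expr
        )
        assert rec.loc[0, "expression_scaled"] == "undetected"


class TestSummarize:
    def _records(self):
        return pd.DataFrame(
            [
                {"rsid": "rs1", "gene_id": "G1", "cell_type": "A", "locus_id": "L0",
                 "mechanism": "loop"},
                {"rsid": "rs1", "gene_id": "G2", "cell_type": "B", "locus_id": "L0",
                 "mechanism": "promoter"},
                {"rsid": "rs2", "gene_id": "G1", "cell_type": "A", "locus_id": "L1",
                 "mechanism": "loop"},
            ]
        )

    def test_single_record_counts(self):
        rec = self._records().iloc[:1]
        tables = summarize(rec, pd.DataFrame())
        locus = tables["locus"]
        assert locus.loc[0, ["n_proxies", "n_genes", "n_cell_types"]].tolist() == [1, 1, 1]

    def test_counts_match_groupby_oracle(self, default_dataset):
        ds = default_dataset
        rec = map_variants_to_genes(load_proxies(ds.proxies), ds.assets)
        tables = summarize(rec, ds.proxies)
        # independent aggregation
        for r in tables["locus"].itertuples(index=False):
            sub = rec[rec["locus_id"] == r.locus_id]
            assert r.n_proxies == sub["rsid"].nunique()
            assert r.n_genes == sub["gene_id"].nunique()
            assert r.n_cell_types == sub["cell_type"].nunique()
        variant = tables["variant"]
        assert (variant["multi_cell_type"].sum()
                + (~variant["multi_cell_type"]).sum()) == rec["rsid"].nunique()

    def test_order_invariance(self):
        rec = self._records()
        shuffled = rec.sample(frac=1, random_state=0).reset_index(drop=True)
        t1 = summarize(rec, pd.DataFrame())
        t2 = summarize(shuffled, pd.DataFrame())
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])

    def test_unknown_cell_type_labelled_other(self):
        tables = summarize(self._records(), pd.DataFrame(), cell_type_systems={"A": "immune"})
        gene = tables["gene"].set_index("gene_id")
        assert gene.loc["G2", "systems"] == "other"
        assert "immune" in gene.loc["G1", "systems"]


class TestScaleExpression:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0.0, 50.0, 100.0], [0.0, 50.0, 100.0]),
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
            ([2.0, 4.0, 10.0], [0.0, 25.0, 100.0]),
        ],
    )
    def test_column_scaling(self, column, expected):
        out = scale_expression(pd.DataFrame({"CT": column}))
        assert np.allclose(out["CT"].to_numpy(), expected)

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            scale_expression(pd.DataFrame({"CT": [-1.0, 2.0]}))

    def test_per_cell_type_independence(self):
        df = pd.DataFrame({"A": [0.0, 10.0], "B": [100.0, 300.0]})
        out = scale_expression(df)
        assert out["A"].tolist() == [0.0, 100.0]
        assert out["B"].tolist() == [0.0, 100.0]
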