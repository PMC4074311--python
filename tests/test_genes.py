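import numpy as np
import pandas as pd
import pytest

from methylshift.genes import (
    DMG,
    associate,
    feature_enrichment,
    intersect_with_expression,
    overlap_enrichment_sets,
    partition,
    shared_genes,
    stable_genes,
)
from methylshift.io import GeneModel, IntervalTrack, ValidationError
from tests.conftest import site_index


def dmr_frame(rows):
    """rows: (chrom, start, end, delta)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "delta"])
    df["z"] = np.sign(df["delta"]) * 5.0
    df["n_obs_sites"] = 3
    df.index.name = "frag_id"
    return df


GENE = GeneModel("geneA", "chr1", "+", 50_000, 60_000, [(50_000, 52_000), (58_000, 60_000)])


class TestAssociate:
    def test_tss_window_inclusive_boundary(self):
        near = dmr_frame([("chr1", 45_900, 46_000, 0.2)])   # 4 kb upstream of TSS
        far = dmr_frame([("chr1", 43_000, 44_000, 0.2)])    # 6 kb upstream
        assert [d.gene_id for d in associate(near, [GENE])] == ["geneA"]
        assert associate(far, [GENE]) == []
        exact = dmr_frame([("chr1", 44_900, 45_001, 0.2)])  # last base at 45_000 -> 5 kb
        assert [d.gene_id for d in associate(exact, [GENE])] == ["geneA"]

    def test_intronic_overlap_associates(self):
        mid = dmr_frame([("chr1", 55_000, 55_200, -0.3)])
        dmgs = associate(mid, [GENE])
        assert dmgs[0].gene_id == "geneA" and dmgs[0].direction == "hypo_in_A"

    def test_one_dmr_supports_multiple_genes_and_dedup(self):
        g2 = GeneModel("geneB", "chr1", "-", 55_000, 70_000)
        dmrs = dmr_frame([("chr1", 55_100, 55_200, 0.2), ("chr1", 59_000, 59_100, 0.3)])
        dmgs = {d.gene_id: d for d in associate(dmrs, [GENE, g2])}
        assert set(dmgs) == {"geneA", "geneB"}
        assert len(dmgs["geneA"].dmr_ids) == 2

    def test_mixed_direction_flagged(self):
        dmrs = dmr_frame([("chr1", 51_000, 51_100, 0.2), ("chr1", 55_000, 55_100, -0.2)])
        assert associate(dmrs, [GENE])[0].direction == "mixed"

    def test_matches_bruteforce_interval_geometry(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(300):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 5_000_000))
            e = s + int(rng.integers(500, 20_000))
            genes.append(GeneModel(f"g{i}", chrom, "+" if rng.random() < 0.5 else "-", s, e))
        rows = []
        for _ in range(300):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 5_000_000))
            rows.append((chrom, s, s + int(rng.integers(50, 400)), float(rng.normal())))
        dmrs = dmr_frame(rows)
        got = {(d.gene_id, tuple(sorted(d.dmr_ids))) for d in associate(dmrs, genes, 5000)}
        # oracle: all-pairs check of the two geometric predicates
        expect = {}
        for fid, row in dmrs.iterrows():
            for g in genes:
                if g.chrom != row["chrom"]:
                    continue
                overlap = row["start"] < g.end and g.start < row["end"]
                if row["start"] <= g.tss < row["end"]:
                    dist = 0
                else:
                    dist = min(abs(g.tss - row["start"]), abs(g.tss - (row["end"] - 1)))
                if overlap or dist <= 5000:
                    expect.setdefault(g.gene_id, []).append(fid)
        expect = {(gid, tuple(sorted(fids))) for gid, fids in expect.items()}
        assert got == expect


class TestPartition:
    def test_published_style_percentage(self):
        dmgs = [DMG(f"x{i}", "chrX", "chrX", "hyper_in_A") for i in range(348)]
        dmgs += [DMG(f"y{i}", "chrX", "chrX", "hypo_in_A") for i in range(72)]
        tab = partition(dmgs)
        row = tab[(tab["chrom_class"] == "chrX") & (tab["direction"] == "hyper_in_A")]
        assert row["percent"].iloc[0] == 82.86

    def test_all_one_direction_and_empty(self):
        dmgs = [DMG("a", "chr1", "autosome", "hyper_in_A")]
        tab = partition(dmgs)
        row = tab[(tab["chrom_class"] == "autosome") & (tab["direction"] == "hyper_in_A")]
        assert row["percent"].iloc[0] == 100.0
        empty = partition([])
        assert (empty["count"] == 0).all() and (empty["percent"] == 0).all()


def mk_dmg(gene, interval, delta, chrom="chr1"):
    cls = "chrX" if chrom == "chrX" else "autosome"
    return DMG(gene, chrom, cls, "hyper_in_A" if delta > 0 else "hypo_in_A",
               dmr_ids=[0], intervals=[interval], deltas=[delta])


class TestSetLogic:
    def test_shared_requires_overlap_and_same_sign(self):
        a = [mk_dmg("g1", (100, 200), 0.2)]
        same = [mk_dmg("g1", (150, 250), 0.3)]
        disjoint = [mk_dmg("g1", (300, 400), 0.3)]
        flipped = [mk_dmg("g1", (150, 250), -0.3)]
        assert shared_genes(a, same) == ["g1"]
        assert shared_genes(a, disjoint) == []
        assert shared_genes(a, flipped) == []

    def test_shared_symmetric(self):
        a = [mk_dmg("g1", (100, 200), 0.2), mk_dmg("g2", (500, 600), -0.1)]
        b = [mk_dmg("g1", (150, 250), 0.3), mk_dmg("g3", (0, 50), 0.1)]
        assert shared_genes(a, b) == shared_genes(b, a)

    def test_stable_genes_gene_level_intersection(self):
        early = [mk_dmg("nap1", (100, 200), -0.12), mk_dmg("flip", (400, 500), 0.22)]
        late = [mk_dmg("nap1", (900, 1000), -0.12), mk_dmg("flip", (400, 500), -0.13),
                mk_dmg("lateonly", (0, 50), 0.4)]
        tab = stable_genes(early, late).set_index("gene_id")
        assert set(tab.index) == {"nap1", "flip"}  # different coordinates still stable
        assert bool(tab.loc["nap1", "same_direction"])
        assert not bool(tab.loc["flip", "same_direction"])

    def test_stable_genes_feature_flags(self):
        g = GeneModel("nap1", "chr1", "+", 80, 1200)
        cgi = IntervalTrack.from_pairs("cpg_island", [("chr1", 120, 180)])
        early = [mk_dmg("nap1", (100, 200), -0.1)]
        late = [mk_dmg("nap1", (900, 1000), -0.1)]
        tab = stable_genes(early, late, genes=[g], cpg_islands=cgi).set_index("gene_id")
        assert bool(tab.loc["nap1", "gene_body"])
        assert bool(tab.loc["nap1", "cpg_island"])
        assert bool(tab.loc["nap1", "promoter"])  # early DMR covers TSS window


class TestFeatureEnrichment:
    def test_direction_of_enrichment(self):
        bg = site_index([("chr1", p, "+") for p in range(0, 2000, 10)])
        inside = site_index([("chr1", p, "+") for p in range(0, 500, 10)])
        track = IntervalTrack.from_pairs("feat", [("chr1", 0, 510)])
        tab = feature_enrichment(inside, bg, [track]).set_index("feature")
        assert tab.loc["feat", "odds_ratio"] > 1
        assert tab.loc["feat", "p"] < 1e-6
        # counts margins match the definitions
        assert tab.loc["feat", "a"] + tab.loc["feat", "b"] == len(inside)
        assert tab.loc["feat", "c"] + tab.loc["feat", "d"] == len(bg)

    def test_background_like_dmrs_not_enriched(self):
        bg = site_index([("chr1", p, "+") for p in range(0, 2000, 10)])
        sub = bg[::4]
        track = IntervalTrack.from_pairs("feat", [("chr1", 0, 1000)])
        tab = feature_enrichment(sub, bg, [track])
        assert tab["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=0.25)

    def test_subset_precondition(self):
        bg = site_index([("chr1", 0, "+")])
        outside = site_index([("chr2", 0, "+")])
        with pytest.raises(ValidationError):
            feature_enrichment(outside, bg, [IntervalTrack.from_pairs("f", [("chr1", 0, 1)])])

    def test_gene_derived_features(self):
        g = GeneModel("g", "chr1", "+", 0, 300, [(0, 100), (200, 300)])
        bg = site_index([("chr1", p, "+") for p in range(0, 600, 10)])
        dmr = site_index([("chr1", p, "+") for p in range(100, 200, 10)])  # intron
        tab = feature_enrichment(dmr, bg, [], genes=[g]).set_index("feature")
        assert set(tab.index) == {"gene_body", "exon", "intron"}
        assert tab.loc["intron", "odds_ratio"] > 1


class TestExpressionAndOverlap:
    def test_intersection_carries_both_effects(self):
        dmgs = [mk_dmg("Ppp2r5c", (0, 10), 0.10), mk_dmg("Other", (0, 10), 0.2)]
        de = pd.DataFrame({"gene_id": ["Ppp2r5c", "Missing"],
                           "log2fc": [1.07, 2.0], "p": [9.7e-5, 0.01]})
        tab = intersect_with_expression(dmgs, de)
        assert tab["gene_id"].tolist() == ["Ppp2r5c"]
        assert tab["log2fc"].iloc[0] == 1.07 and tab["delta_me"].iloc[0] == 0.10

    def test_duplicate_expression_ids_warn(self):
        dmgs = [mk_dmg("A", (0, 10), 0.1)]
        de = pd.DataFrame({"gene_id": ["A", "A"], "log2fc": [1, 2], "p": [0.1, 0.2]})
        with pytest.warns(UserWarning):
            tab = intersect_with_expression(dmgs, de)
        assert len(tab) == 1

    def test_overlap_fold_algebra(self):
        ids = [f"g{i}" for i in range(10)]
        r = overlap_enrichment_sets(ids, ids, 40)
        assert r.fold == pytest.approx(4.0)  # universe / |A|
        assert overlap_enrichment_sets(ids[:5], ids[5:], 40).fold == 0.0

    def test_universe_validation_and_enumeration(self):
        with pytest.raises(ValidationError):
            overlap_enrichment_sets(["a", "b"], ["c"], 2)
        # k=2, |A|=4, |B|=5, N=20 against direct pmf summation
        from scipy.stats import hypergeom
        a = [f"x{i}" for i in range(4)]
        b = a[:2] + [f"y{i}" for i in range(3)]
        r = overlap_enrichment_sets(a, b, 20)
        expect = sum(hypergeom.pmf(k, 20, 5, 4) for k in (2, 3, 4))
        assert r.p == pytest.approx(expect, rel=1e-9)
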