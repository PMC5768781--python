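"""Genomic-context labelling, enrichment and gene over-representation."""

import math

import numpy as np
import pandas as pd
import pytest

from epihet.annotation import (
    GeneModel,
    annotate_cpgs,
    context_enrichment,
    gene_body_overrepresentation,
    geneset_overlap_test,
)
from epihet.methylio import ValidationError, sites_frame
from epihet.stats import bh_adjust


def make_sites(positions, chrom="chr1", strand="+"):
    return sites_frame([f"{chrom}:{p}:{strand}" for p in positions])


GENE = GeneModel("g1", "chr1", "+", tss=50_000, tes=60_000,
                 exons=[(50_000, 50_300), (59_000, 59_300)])
ISLAND = ("chr1", 100_000, 100_600)  # 1-based closed


class TestAnnotateCpGs:
    def test_feature_bands(self):
        sites = make_sites([
            50_000,   # at TSS -> promoter
            48_500,   # within 2 kb upstream -> promoter
            59_100,   # exon, 9.1 kb from TSS -> exon (past promoter window)
            55_000,   # inside gene, no exon -> intron
            90_000,   # far away -> intergenic
        ])
        labels = annotate_cpgs(sites, [GENE], [ISLAND])
        assert list(labels["feature"]) == [
            "promoter", "promoter", "exon", "intron", "intergenic"]

    def test_island_distance_bands(self):
        sites = make_sites([
            100_300,             # inside -> island
            100_600 + 1_500,     # 1.5 kb past the edge -> shore
            100_600 + 3_000,     # -> shelf
            100_600 + 5_000,     # -> open sea
            100_000 - 2_000,     # 2 kb before the start -> shore (boundary)
        ])
        labels = annotate_cpgs(sites, [GENE], [ISLAND])
        assert list(labels["island_context"]) == [
            "island", "shore", "shelf", "open_sea", "shore"]

    def test_exon_beats_intron_but_not_promoter(self):
        sites = make_sites([50_100])  # in exon 1 AND the promoter window
        labels = annotate_cpgs(sites, [GENE], [ISLAND])
        assert labels["feature"].iloc[0] == "promoter"

    def test_unannotated_chromosome_warns_and_defaults(self):
        sites = make_sites([123], chrom="chrUn")
        with pytest.warns(UserWarning, match="chrUn"):
            labels = annotate_cpgs(sites, [GENE], [ISLAND])
        assert labels["feature"].iloc[0] == "intergenic"
        assert labels["island_context"].iloc[0] == "open_sea"

    def test_labels_partition_all_sites(self, sim_result, sim_matrix):
        labels = annotate_cpgs(sim_matrix.sites, sim_result.genes,
                               sim_result.islands)
        assert labels["feature"].value_counts().sum() == len(labels)
        assert labels["island_context"].value_counts().sum() == len(labels)


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct enumeration with exact binomials."""
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        for x in range(k, min(K, n) + 1)
    )


def fisher_oracle(a, b, c, d):
    n, r1, c1 = a + b + c + d, a + b, a + c
    def pmf(x):
        return math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = pmf(a)
    return sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-7))


class TestContextEnrichment:
    def _labels(self, promoter_n, other_n):
        keys = [f"chr1:{i + 1}:+" for i in range(promoter_n + other_n)]
        return pd.DataFrame(
            {"feature": ["promoter"] * promoter_n + ["intron"] * other_n,
             "island_context": ["open_sea"] * (promoter_n + other_n)},
            index=pd.Index(keys, name="site"))

    def test_identically_distributed_signature_flat(self):
        labels = self._labels(100, 300)
        # signature = every 4th site: same composition as the background
        sig = labels.index[::4]
        rows = context_enrichment(sig, labels)
        feature_rows = rows[rows["partition"] == "feature"]
        present = feature_rows[feature_rows["signature_count"] > 0]
        assert (present["pvalue"] > 0.5).all()

    def test_p_matches_enumeration_oracle(self):
        labels = self._labels(promoter_n=80, other_n=420)
        # signature: 30 of 100 in promoters; background 50/400
        sig = labels.index[:30].append(labels.index[80:150])
        rows = context_enrichment(sig, labels)
        row = rows[(rows["partition"] == "feature")
                   & (rows["category"] == "promoter")].iloc[0]
        assert row["signature_count"] == 30
        assert row["background_count"] == 50
        assert row["pvalue"] == pytest.approx(fisher_oracle(30, 70, 50, 350),
                                              abs=1e-12)

    def test_empty_signature_reports_ones(self):
        labels = self._labels(10, 10)
        with pytest.warns(UserWarning, match="empty signature"):
            rows = context_enrichment(pd.Index([]), labels)
        assert (rows["pvalue"] == 1.0).all()

    def test_absent_category_gets_p_one(self):
        labels = self._labels(10, 10)  # no exon/intergenic sites at all
        rows = context_enrichment(labels.index[:5], labels)
        exon = rows[(rows["partition"] == "feature")
                    & (rows["category"] == "exon")].iloc[0]
        assert exon["signature_count"] == 0 and exon["pvalue"] == 1.0


class TestGeneBodyOverrepresentation:
    def test_p_matches_enumeration_oracle(self):
        # population 100 CpGs, 20 in signature, body holds 10 of which 8 signature
        sites = make_sites(list(range(1000, 101_000, 1000)))  # 100 sites
        body_sites = sites.index[:10]  # positions 1000..10000
        signature = body_sites[:8].append(sites.index[50:62])  # 8 + 12 = 20
        gene = GeneModel("g", "chr1", "+", tss=1, tes=10_000, exons=[])
        table = gene_body_overrepresentation(signature, sites, [gene], offset=0)
        row = table.iloc[0]
        assert (row["n_total_cpgs_in_body"], row["n_signature_cpgs_in_body"]) == (10, 8)
        assert row["pvalue"] == pytest.approx(
            hypergeom_tail_oracle(8, 100, 20, 10), abs=1e-12)

    def test_zero_signature_in_body_gives_full_tail(self):
        sites = make_sites(list(range(1000, 101_000, 1000)))
        signature = sites.index[50:70]
        gene = GeneModel("g", "chr1", "+", tss=1, tes=10_000, exons=[])
        table = gene_body_overrepresentation(signature, sites, [gene], offset=0)
        assert table.iloc[0]["pvalue"] == pytest.approx(1.0)

    def test_gene_without_cpgs_excluded(self):
        sites = make_sites([1000, 2000])
        gene = GeneModel("empty", "chr1", "+", tss=500_000, tes=510_000, exons=[])
        table = gene_body_overrepresentation(sites.index[:1], sites, [gene])
        assert len(table) == 0

    def test_body_is_strand_aware(self):
        # minus-strand gene: body runs [TES, TSS - offset] = [1000, 8000],
        # so the site at 1500 is inside and the one at 8500 is not
        sites = make_sites([1_500, 8_500])
        gene = GeneModel("g", "chr1", "-", tss=10_000, tes=1_000, exons=[])
        table = gene_body_overrepresentation(sites.index, sites, [gene],
                                             offset=2_000)
        assert table.iloc[0]["n_total_cpgs_in_body"] == 1

    def test_recovers_planted_enriched_genes(self, sim_result, sim_matrix,
                                             sim_signature):
        table = gene_body_overrepresentation(sim_signature.sites,
                                             sim_matrix.sites, sim_result.genes)
        hits = set(table.loc[table["significant"], "gene_id"])
        enriched = set(sim_result.truth.enriched_genes)
        assert len(hits & enriched) / len(enriched) >= 0.80


def test_bh_adjustment_step_up_oracle():
    adjusted = bh_adjust([0.01, 0.02, 0.03])
    assert adjusted == pytest.approx([0.03, 0.03, 0.03])
    # monotone after the step-up minimum
    rng = np.random.default_rng(0)
    p = np.sort(rng.random(50))
    adj = bh_adjust(p)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj >= p - 1e-12).all()


class TestGenesetOverlap:
    def test_forced_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        overlap, p = geneset_overlap_test(universe, universe, universe)
        assert overlap == 20 and p == pytest.approx(1.0)

    def test_disjoint_sets_not_significant(self):
        universe = [f"g{i}" for i in range(10)]
        _, p = geneset_overlap_test(universe[:4], universe[4:8], universe)
        assert p > 0.5

    def test_p_matches_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(50)]
        a, b = universe[:10], universe[4:14]  # overlap 6
        overlap, p = geneset_overlap_test(a, b, universe)
        assert overlap == 6
        assert p == pytest.approx(hypergeom_tail_oracle(6, 50, 10, 10), abs=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValidationError):
            geneset_overlap_test([], [], [])
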