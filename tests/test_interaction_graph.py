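"""Categorization, aggregation, evidence overlay and query tests."""

import numpy as np
import pytest

from ldgi.feature_annotation import FeatureAnnotation
from ldgi.interaction_graph import (
    CATEGORIES,
    CDS_CDS_SUBTYPES,
    build_interactions,
    categorize_pair,
    overlay_evidence,
    parse_region,
    query_interactions,
    query_pairs,
)
from ldgi.io_formats import HotspotTrack, SNPRecord
from ldgi.ld_core import LDStatistics
from ldgi.lrld_scan import LRLDPair


def ann(snp_id, gene, feature, effect=None, side=None):
    tid = "" if feature == "PROMOTER" else f"{gene}.t1"
    return FeatureAnnotation(snp_id, gene, tid, feature,
                             utr_side=side, coding_effect=effect)


def make_pair(snp1_id, snp2_id, pop="P", r2=1.0,
              chrom1="chr1", chrom2="chr2", pos1=100, pos2=100):
    stats = LDStatistics(0.5, 0.5, 0.5, 0.5, 0.5, 0.25, 1.0, r2, 40, 0, 0)
    return LRLDPair(
        SNPRecord(chrom1, pos1, snp1_id, "A", "G"),
        SNPRecord(chrom2, pos2, snp2_id, "A", "G"),
        pop, stats, "DIFF_CHROM",
    )


class TestCategorize:
    def test_promoter_cds_with_effect(self):
        cat, sub = categorize_pair(
            ann("s1", "gA", "PROMOTER"),
            ann("s2", "gB", "CDS", "NONSYNONYMOUS"),
        )
        assert (cat, sub) == ("PROMOTER-CDS", "NONSYN-NA")

    def test_cds_cds_mixed_effects(self):
        cat, sub = categorize_pair(
            ann("s1", "gA", "CDS", "SYNONYMOUS"),
            ann("s2", "gB", "CDS", "NONSYNONYMOUS"),
        )
        assert (cat, sub) == ("CDS-CDS", "NONSYN-SYN")

    def test_utr_utr_no_subtype(self):
        cat, sub = categorize_pair(
            ann("s1", "gA", "UTR", side=5), ann("s2", "gB", "UTR", side=3)
        )
        assert (cat, sub) == ("UTR-UTR", "NA")

    def test_canonical_order_swap_invariant(self):
        a = ann("s1", "gA", "UTR", side=3)
        b = ann("s2", "gB", "PROMOTER")
        assert categorize_pair(a, b) == categorize_pair(b, a) \
            == ("PROMOTER-UTR", "NA")


class TestBuildInteractions:
    def test_single_pair_single_interaction(self):
        pairs = [make_pair("s1", "s2")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s2": [ann("s2", "gB", "CDS", "SYNONYMOUS")],
        }
        ldgis, counters = build_interactions(pairs, annotations)
        assert len(ldgis) == 1
        g = ldgis[0]
        assert (g.gene1, g.gene2) == ("gA", "gB")
        assert g.category == "PROMOTER-CDS" and g.coding_subtype == "SYN-NA"
        assert g.support_count == 1

    def test_overlapping_gene_second_interaction(self):
        pairs = [make_pair("s1", "s2")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s2": [ann("s2", "gB", "CDS", "SYNONYMOUS"),
                   ann("s2", "gC", "UTR", side=3)],
        }
        ldgis, _ = build_interactions(pairs, annotations)
        cats = {(g.gene1, g.gene2): g.category for g in ldgis}
        assert cats == {("gA", "gB"): "PROMOTER-CDS",
                        ("gA", "gC"): "PROMOTER-UTR"}

    def test_self_pair_dropped_with_counter(self):
        pairs = [make_pair("s1", "s2")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s2": [ann("s2", "gA", "CDS", "SYNONYMOUS")],
        }
        ldgis, counters = build_interactions(pairs, annotations)
        assert ldgis == [] and counters.self_pairs == 1

    def test_aggregation_counts_distinct_pairs(self):
        pairs = [make_pair("s1", "s2"), make_pair("s3", "s4")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s3": [ann("s3", "gA", "PROMOTER")],
            "s2": [ann("s2", "gB", "PROMOTER")],
            "s4": [ann("s4", "gB", "PROMOTER")],
        }
        ldgis, _ = build_interactions(pairs, annotations)
        assert len(ldgis) == 1
        assert ldgis[0].support_count == 2
        assert ldgis[0].supporting_pairs == ("s1|s2", "s3|s4")

    def test_count_law_upper_bound(self):
        pairs = [make_pair("s1", "s2")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER"), ann("s1", "gB", "UTR", side=5)],
            "s2": [ann("s2", "gC", "CDS", "SYNONYMOUS"),
                   ann("s2", "gA", "UTR", side=3)],
        }
        ldgis, counters = build_interactions(pairs, annotations)
        assert len(ldgis) + counters.self_pairs <= 4
        assert counters.self_pairs == 1  # gA x gA combination

    def test_symmetry_under_snp_order_swap(self):
        annotations = {
            "s1": [ann("s1", "gA", "CDS", "NONSYNONYMOUS")],
            "s2": [ann("s2", "gB", "UTR", side=5)],
        }
        fwd, _ = build_interactions([make_pair("s1", "s2")], annotations)
        # same pair entered with loci swapped (canonical order re-imposed)
        rev, _ = build_interactions(
            [make_pair("s2", "s1", chrom1="chr2", chrom2="chr1")], annotations
        )
        key = lambda g: (g.gene1, g.gene2, g.category, g.coding_subtype)
        assert [key(g) for g in fwd] == [key(g) for g in rev]

    def test_populations_kept_separate(self):
        pairs = [make_pair("s1", "s2", pop="P1"), make_pair("s1", "s2", pop="P2")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s2": [ann("s2", "gB", "PROMOTER")],
        }
        ldgis, _ = build_interactions(pairs, annotations)
        assert sorted(g.population_label for g in ldgis) == ["P1", "P2"]

    def test_category_closure(self, default_bundle):
        from ldgi.lrld_scan import scan_population

        b = default_bundle
        pairs, _ = scan_population(b.panel, b.track, 0.8)
        annotations = {
            sid: [FeatureAnnotation(
                sid, p["gene_id"], p["transcript_id"],
                "UTR" if p["feature"].startswith("UTR") else p["feature"],
                utr_side=int(p["feature"][3:]) if p["feature"].startswith("UTR")
                else None,
                coding_effect=p["coding_effect"])
                for p in placements]
            for sid, placements in b.manifest.placements.items()
        }
        ldgis, _ = build_interactions(pairs, annotations)
        assert ldgis
        for g in ldgis:
            assert g.category in CATEGORIES
            if g.category == "CDS-CDS":
                assert g.coding_subtype in CDS_CDS_SUBTYPES


class TestEvidenceOverlay:
    def build(self):
        pairs = [make_pair("s1", "s2"), make_pair("s3", "s4")]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s2": [ann("s2", "gB", "PROMOTER")],
            "s3": [ann("s3", "gC", "PROMOTER")],
            "s4": [ann("s4", "gD", "PROMOTER")],
        }
        ldgis, _ = build_interactions(pairs, annotations)
        return ldgis

    def test_unordered_ppi_match(self):
        ldgis = self.build()
        flagged, _ = overlay_evidence(ldgis, ppi_pairs={frozenset(("gB", "gA"))})
        by_pair = {(g.gene1, g.gene2): g.evidence_flags for g in flagged}
        assert by_pair[("gA", "gB")] == {"KNOWN_PPI"}
        assert by_pair[("gC", "gD")] == frozenset()

    def test_trait_linked_via_supporting_snp(self):
        ldgis = self.build()
        flagged, _ = overlay_evidence(ldgis, snp_traits={"s4": ["height"]})
        by_pair = {(g.gene1, g.gene2): g.evidence_flags for g in flagged}
        assert by_pair[("gC", "gD")] == {"TRAIT_LINKED"}

    def test_unknown_genes_counted(self):
        ldgis = self.build()
        _, counters = overlay_evidence(
            ldgis, ppi_pairs={frozenset(("gX", "gY"))}
        )
        assert counters["unknown_evidence_genes"] == 1

    def test_idempotence(self):
        ldgis = self.build()
        evidence = dict(ppi_pairs={frozenset(("gA", "gB"))},
                        snp_traits={"s1": ["t"]})
        once, _ = overlay_evidence(ldgis, **evidence)
        twice, _ = overlay_evidence(once, **evidence)
        assert once == twice


class TestQueries:
    def setup_method(self):
        self.pairs = [
            make_pair("s1", "s2", pos1=500),
            make_pair("s3", "s4", pop="P2", chrom1="chr3", pos1=50),
        ]
        annotations = {
            "s1": [ann("s1", "gA", "PROMOTER")],
            "s2": [ann("s2", "gB", "CDS", "SYNONYMOUS")],
            "s3": [ann("s3", "gA", "UTR", side=3)],
            "s4": [ann("s4", "gC", "UTR", side=5)],
        }
        self.ldgis, _ = build_interactions(self.pairs, annotations)

    def test_query_by_gene(self):
        hits = query_interactions(self.ldgis, gene_id="gA")
        assert len(hits) == 2

    def test_region_query_half_open(self):
        assert len(query_pairs(self.pairs, region="chr1:0-500")) == 0
        assert len(query_pairs(self.pairs, region="chr1:0-501")) == 1

    def test_intersection_semantics(self):
        hits = query_interactions(
            self.ldgis, categories={"UTR-UTR"}, populations={"P2"}
        )
        assert [(g.gene1, g.gene2) for g in hits] == [("gA", "gC")]
        assert query_interactions(
            self.ldgis, categories={"UTR-UTR"}, populations={"P"}
        ) == []

    def test_query_by_snp(self):
        assert len(query_pairs(self.pairs, snp_id="s3")) == 1

    def test_malformed_region_is_error(self):
        with pytest.raises(ValueError):
            parse_region("chr1:abc")
        with pytest.raises(ValueError):
            query_pairs(self.pairs, region="chr1-0:10")
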