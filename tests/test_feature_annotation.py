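"""Promoter geometry, feature placement and coding-effect tests."""

import pytest

from conftest import CODON_TABLE
from ldgi.feature_annotation import (
    GeneAnnotator,
    RefMismatchError,
    coding_effect,
    promoter_interval,
)
from ldgi.io_formats import (
    GeneModel,
    SNPRecord,
    TranscriptModel,
    reverse_complement,
)


def make_gene(gene_id, strand, tss, transcripts=()):
    return GeneModel(gene_id, gene_id, "chr1", strand, tss, list(transcripts))


class TestPromoterInterval:
    def test_plus_strand(self):
        assert promoter_interval(make_gene("g", "+", 10_000)) == (8000, 10_000)

    def test_minus_strand_mirrors(self):
        assert promoter_interval(make_gene("g", "-", 5000)) == (5001, 7001)

    def test_clamped_at_chromosome_start(self):
        assert promoter_interval(make_gene("g", "+", 1500)) == (0, 1500)

    def test_clamped_at_chromosome_end(self):
        g = make_gene("g", "-", 9000)
        assert promoter_interval(g, chrom_length=10_000) == (9001, 10_000)

    def test_length_is_2kb_unless_clamped(self):
        s, e = promoter_interval(make_gene("g", "+", 50_000))
        assert e - s == 2000
        s, e = promoter_interval(make_gene("g", "-", 50_000))
        assert e - s == 2000


class TestCodingEffect:
    def plus_transcript(self, cds_seq):
        return TranscriptModel("t", "+", [(0, len(cds_seq))],
                               [(0, len(cds_seq))], cds_sequence=cds_seq)

    @pytest.mark.parametrize(
        "codon, pos, ref, alt, expected",
        [
            ("CAT", 1, "A", "G", "NONSYNONYMOUS"),  # His -> Arg
            ("AAA", 2, "A", "G", "SYNONYMOUS"),     # Lys -> Lys
            ("TAC", 2, "C", "A", "NONSYNONYMOUS"),  # Tyr -> stop
        ],
    )
    def test_plus_strand_codon_changes(self, codon, pos, ref, alt, expected):
        tr = self.plus_transcript(codon)
        snp = SNPRecord("chr1", pos, "s", ref, alt)
        assert coding_effect(snp, tr) == expected

    def test_minus_strand_two_exon_transcript(self):
        # transcript CDS (reading order) = ATG CTC; genomic layout:
        # exon at [10,13) holds revcomp("ATG") = CAT, exon at [0,3) holds
        # revcomp("CTC") = GAG; the SNP hits genomic pos 0 (CDS offset 5).
        tr = TranscriptModel("t", "-", [(0, 3), (10, 13)], [(0, 3), (10, 13)],
                             cds_sequence="ATGCTC")
        snp = SNPRecord("chr1", 0, "s", "G", "A")  # codon CTC -> CTT
        assert coding_effect(snp, tr) == "SYNONYMOUS"

    def test_ref_mismatch_is_hard_error(self):
        tr = self.plus_transcript("CAT")
        snp = SNPRecord("chr1", 0, "s", "G", "A")  # genome says C
        with pytest.raises(RefMismatchError, match="s"):
            coding_effect(snp, tr)

    def test_codon_oracle_spot_checks(self):
        """Sample of the full-enumeration oracle (all 576 in acceptance)."""
        bases = "ACGT"
        for codon in ("CTG", "TGG", "ATG", "TAA", "AGA"):
            for pos in range(3):
                for alt in bases:
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1:]
                    expected = (
                        "SYNONYMOUS"
                        if CODON_TABLE[codon] == CODON_TABLE[mutated]
                        else "NONSYNONYMOUS"
                    )
                    tr = self.plus_transcript(codon)
                    snp = SNPRecord("chr1", pos, "s", codon[pos], alt)
                    assert coding_effect(snp, tr) == expected

    def test_strand_consistency(self):
        """A codon change reads identically from either strand's gene model."""
        codon, pos, ref, alt = "GAC", 0, "G", "C"  # Asp -> His
        plus = self.plus_transcript(codon)
        fwd = coding_effect(SNPRecord("chr1", pos, "s", ref, alt), plus)
        minus = TranscriptModel("t", "-", [(0, 3)], [(0, 3)],
                                cds_sequence=codon)
        comp = dict(zip("ACGT", "TGCA"))
        rev = coding_effect(
            SNPRecord("chr1", 2 - pos, "s", comp[ref], comp[alt]), minus
        )
        assert fwd == rev == "NONSYNONYMOUS"


class TestAnnotateSnp:
    @pytest.fixture
    def annotator(self):
        # geneA '+': exon1 [1000,1060) with 5'UTR [1000,1030) + CDS start,
        # exon2 [1100,1160) with CDS end + 3'UTR [1130,1160)
        ga_t = TranscriptModel(
            "gA.t1", "+", [(1000, 1060), (1100, 1160)],
            [(1030, 1060), (1100, 1130)],
            cds_sequence="ATG" + "A" * 57,
        )
        gene_a = GeneModel("gA", "gA", "chr1", "+", 1000, [ga_t])
        # geneB '-' overlaps geneA: its single exon covers geneA's CDS SNP
        # shared genome: [1020,1030) = C*10, [1030,1050) = gA's ATG + A*17
        gb_t = TranscriptModel(
            "gB.t1", "-", [(1010, 1070)], [(1020, 1050)],
            cds_sequence=reverse_complement("C" * 10 + "ATG" + "A" * 17),
        )
        gene_b = GeneModel("gB", "gB", "chr1", "-", 1069, [gb_t])
        return GeneAnnotator([gene_a, gene_b], {"chr1": 10_000})

    def test_overlapping_genes_both_reported(self, annotator):
        snp = SNPRecord("chr1", 1035, "s", "A", "G")
        anns = annotator.annotate(snp)
        assert {(a.gene_id, a.feature) for a in anns} == {
            ("gA", "CDS"), ("gB", "CDS"),
        }

    def test_promoter_only_annotation(self, annotator):
        snp = SNPRecord("chr1", 500, "s", "A", "G")
        anns = annotator.annotate(snp)
        assert len(anns) == 1
        assert anns[0].feature == "PROMOTER" and anns[0].transcript_id == ""

    def test_intergenic_snp_empty(self, annotator):
        assert annotator.annotate(SNPRecord("chr1", 9000, "s", "A", "G")) == []

    def test_unknown_chromosome_empty(self, annotator):
        assert annotator.annotate(SNPRecord("chrZ", 1035, "s", "A", "G")) == []

    def test_utr_sides_strand_aware(self, annotator):
        five = annotator.annotate(SNPRecord("chr1", 1010, "s", "A", "G"))
        by_gene = {a.gene_id: a for a in five}
        assert by_gene["gA"].feature == "UTR" and by_gene["gA"].utr_side == 5
        # same position is downstream of gB's CDS on the minus strand
        assert by_gene["gB"].feature == "UTR" and by_gene["gB"].utr_side == 3

    def test_cds_xor_utr_within_transcript(self, annotator):
        """Each exonic position maps to exactly one feature per transcript."""

        def genome_base(pos):  # the base layout the fixture genes imply
            if 1030 <= pos < 1033:
                return "ATG"[pos - 1030]
            if 1020 <= pos < 1030:
                return "C"
            return "A"

        for pos in range(1000, 1160):
            ref = genome_base(pos)
            alt = "G" if ref != "G" else "T"
            anns = annotator.annotate(SNPRecord("chr1", pos, "s", ref, alt))
            per_transcript = {}
            for a in anns:
                if a.transcript_id:
                    per_transcript.setdefault(a.transcript_id, []).append(a)
            for found in per_transcript.values():
                assert len(found) == 1


class TestBundlePlacements:
    def test_annotations_match_manifest_prescriptions(self, default_bundle):
        """The annotator reproduces every prescribed feature placement."""
        import pyfaidx

        from ldgi.io_formats import read_gene_models

        b = default_bundle
        genes = read_gene_models(b.paths["gff3"], b.paths["fasta"])
        fa = pyfaidx.Fasta(b.paths["fasta"])
        annotator = GeneAnnotator(genes, {k: len(fa[k]) for k in fa.keys()})
        snps = {s.snp_id: s for s in b.panel.snps}
        for snp_id, expected in b.manifest.placements.items():
            got = {
                (a.gene_id, a.transcript_id, a.feature_label(),
                 a.coding_effect)
                for a in annotator.annotate(snps[snp_id])
            }
            want = {
                (p["gene_id"], p["transcript_id"], p["feature"],
                 p["coding_effect"])
                for p in expected
            }
            assert got == want, snp_id
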