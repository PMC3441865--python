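"""Placement of SNPs in gene features and coding-effect classification.

A SNP is annotated against promoter, UTR and CDS intervals of gene
models.  The promoter is gene-level: the 2 kb immediately upstream of the
gene's 5'-most transcription start, strand-aware and half-open, so the
promoter never overlaps the transcript itself.  Within one transcript an
exonic position is either CDS or UTR (never both); across transcripts and
overlapping genes every placement is reported, which is why a single SNP
pair can surface more than once in the output tables.

Coding SNPs are classified as synonymous or nonsynonymous by substituting
the alternate allele into the containing codon of the spliced CDS and
translating with the standard genetic code; changes that create or
destroy a stop codon count as nonsynonymous (the binary scheme has no
separate nonsense class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import GeneModel, SNPRecord, TranscriptModel

logger = logging.getLogger("ldgi")

PROMOTER = "PROMOTER"
UTR = "UTR"
CDS = "CDS"
SYNONYMOUS = "SYNONYMOUS"
NONSYNONYMOUS = "NONSYNONYMOUS"

PROMOTER_LENGTH = 2000

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class RefMismatchError(Exception):
    """The SNP's reference allele disagrees with the genome sequence."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """One SNP's placement in one gene feature.

    ``transcript_id`` is empty for promoter hits; ``utr_side`` is 5 or 3
    for UTR hits and None otherwise; ``coding_effect`` is set for CDS hits
    on codable transcripts and None otherwise.
    """

    snp_id: str
    gene_id: str
    transcript_id: str
    feature: str
    utr_side: int | None = None
    coding_effect: str | None = None

    def feature_label(self) -> str:
        if self.feature == UTR and self.utr_side is not None:
            return f"UTR{self.utr_side}"
        return self.feature


def promoter_interval(gene: GeneModel,
                      chrom_length: int | None = None) -> tuple[int, int]:
    """The 2 kb upstream of the gene's TSS as a half-open interval.

    Plus strand: [tss-2000, tss); minus strand: [tss+1, tss+2001), i.e.
    the TSS base itself is excluded on both strands.  Clamped to
    chromosome bounds.
    """
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_LENGTH, gene.tss
    else:
        start, end = gene.tss + 1, gene.tss + 1 + PROMOTER_LENGTH
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def _subtract(intervals, holes):
    """Set difference of sorted half-open interval lists."""
    out = []
    for s, e in intervals:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
        if cur < e:
            out.append((cur, e))
    return out


def coding_effect(snp: SNPRecord, transcript: TranscriptModel,
                  cds_sequence: str | None = None) -> str:
    """Classify a CDS SNP as SYNONYMOUS or NONSYNONYMOUS.

    The CDS-relative offset is found by summing spliced segment lengths in
    strand order; on the minus strand the complement of each genomic
    allele enters the codon.  Raises :class:`RefMismatchError` when the
    reference allele disagrees with the CDS sequence at that position.
    """
    seq = transcript.cds_sequence if cds_sequence is None else cds_sequence
    if not transcript.codable:
        raise ValueError(
            f"transcript {transcript.transcript_id} is flagged non-codable"
        )
    segs = transcript.cds_segments
    offset = None
    if transcript.strand == "+":
        acc = 0
        for s, e in segs:
            if s <= snp.pos < e:
                offset = acc + (snp.pos - s)
                break
            acc += e - s
    else:
        acc = 0
        for s, e in reversed(segs):
            if s <= snp.pos < e:
                offset = acc + (e - 1 - snp.pos)
                break
            acc += e - s
    if offset is None:
        raise ValueError(f"SNP {snp.snp_id} is not inside a CDS segment")

    if transcript.strand == "+":
        ref_t, alt_t = snp.ref_allele, snp.alt_allele
    else:
        ref_t, alt_t = _COMP[snp.ref_allele], _COMP[snp.alt_allele]
    if seq[offset] != ref_t:
        raise RefMismatchError(
            f"SNP {snp.snp_id}: reference allele {snp.ref_allele} "
            f"(transcript-strand {ref_t}) disagrees with CDS base "
            f"{seq[offset]} at CDS offset {offset}"
        )
    ci = 3 * (offset // 3)
    cpos = offset % 3
    codon = seq[ci:ci + 3]
    alt_codon = codon[:cpos] + alt_t + codon[cpos + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return SYNONYMOUS if aa_ref == aa_alt else NONSYNONYMOUS


class GeneAnnotator:
    """Interval index over gene models for per-SNP feature lookup."""

    def __init__(self, genes: list[GeneModel],
                 chrom_lengths: dict[str, int] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        self._genes = genes
        chrom_lengths = chrom_lengths or {}
        for gene in genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            ps, pe = promoter_interval(gene, chrom_lengths.get(gene.chrom))
            if ps < pe:
                tree.addi(ps, pe, (PROMOTER, gene, None, None))
            for tr in gene.transcripts:
                for s, e in tr.cds_segments:
                    tree.addi(s, e, (CDS, gene, tr, None))
                if not tr.cds_segments:
                    continue  # non-coding transcript: no UTR to assign
                cds_lo = tr.cds_segments[0][0]
                cds_hi = tr.cds_segments[-1][1]
                for s, e in _subtract(tr.exons, tr.cds_segments):
                    if e <= cds_lo:
                        side = 5 if gene.strand == "+" else 3
                    elif s >= cds_hi:
                        side = 3 if gene.strand == "+" else 5
                    else:
                        logger.warning(
                            "transcript %s: exonic non-CDS interval [%d,%d) "
                            "inside the CDS span; skipped", tr.transcript_id, s, e
                        )
                        continue
                    tree.addi(s, e, (UTR, gene, tr, side))

    def annotate(self, snp: SNPRecord) -> list[FeatureAnnotation]:
        """All (gene, transcript, feature) placements of one SNP.

        A SNP in no feature returns an empty list and contributes nothing
        to gene interactions.
        """
        tree = self._trees.get(snp.chrom)
        if tree is None:
            return []
        out: dict[tuple, FeatureAnnotation] = {}
        for iv in tree.at(snp.pos):
            kind, gene, tr, side = iv.data
            if kind == PROMOTER:
                ann = FeatureAnnotation(snp.snp_id, gene.gene_id, "", PROMOTER)
            elif kind == CDS:
                effect = None
                if tr.codable:
                    effect = coding_effect(snp, tr)
                ann = FeatureAnnotation(
                    snp.snp_id, gene.gene_id, tr.transcript_id, CDS,
                    coding_effect=effect,
                )
            else:
                ann = FeatureAnnotation(
                    snp.snp_id, gene.gene_id, tr.transcript_id, UTR, utr_side=side
                )
            key = (ann.gene_id, ann.transcript_id, ann.feature, ann.utr_side)
            out.setdefault(key, ann)
        return sorted(
            out.values(),
            key=lambda a: (a.gene_id, a.transcript_id, a.feature, a.utr_side or 0),
        )


def annotate_snp(snp: SNPRecord, annotator: GeneAnnotator) -> list[FeatureAnnotation]:
    """Convenience wrapper over :meth:`GeneAnnotator.annotate`."""
    return annotator.annotate(snp)
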