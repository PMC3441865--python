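"""Readers and writers for the external formats the pipeline touches.

Every coordinate is normalized at the I/O boundary to an internal 0-based
half-open convention: VCF and GFF3 positions (1-based) are decremented on
ingest, BED intervals pass through unchanged.  Nothing downstream of this
module ever sees a 1-based coordinate.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .ld_core import MISSING

logger = logging.getLogger("ldgi")

_BASES = frozenset("ACGT")
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SNPRecord:
    """A biallelic SNP locus; ``pos`` is 0-based."""

    chrom: str
    pos: int
    snp_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.snp_id}: negative position {self.pos}")


@dataclass
class HaplotypePanel:
    """Phased allele matrix for one population.

    ``alleles`` has two rows per sample (the phased haplotypes) and one
    column per SNP; entries are 0 (ref), 1 (alt) or :data:`MISSING`.
    Columns are kept sorted by (chrom, pos).
    """

    population_label: str
    sample_ids: list[str]
    snps: list[SNPRecord]
    alleles: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype row count must be 2 x number of samples")
        if self.alleles.shape[1] != len(self.snps):
            raise ValueError("column count must equal number of SNPs")
        order = sorted(range(len(self.snps)), key=lambda j: self.snps[j])
        if order != list(range(len(self.snps))):
            self.snps = [self.snps[j] for j in order]
            self.alleles = self.alleles[:, order]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def column(self, j: int) -> np.ndarray:
        return self.alleles[:, j]


class HotspotTrack:
    """Per-chromosome sorted, merged recombination-hotspot intervals.

    Overlapping or abutting intervals are merged on construction, so the
    long-range criterion counts recombination regions rather than
    bookkeeping fragments.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                merged = self._merge(ivs)
                self._by_chrom[chrom] = merged
                self._starts[chrom] = [s for s, _ in merged]
                self._ends[chrom] = [e for _, e in merged]

    @staticmethod
    def _merge(ivs) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if s >= e:
                raise ValueError(f"degenerate interval [{s}, {e})")
            if out and s <= out[-1][1]:  # overlap or abutment
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    def rank_start_le(self, chrom: str, pos: int) -> int:
        """Number of merged intervals on ``chrom`` with start <= pos."""
        return bisect_right(self._starts.get(chrom, []), pos)

    def rank_end_le(self, chrom: str, pos: int) -> int:
        """Number of merged intervals on ``chrom`` with end <= pos."""
        return bisect_right(self._ends.get(chrom, []), pos)


@dataclass
class TranscriptModel:
    """Exon/CDS geometry of one transcript (0-based half-open intervals)."""

    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]]
    cds_sequence: str = ""  # spliced, reading-frame order
    codable: bool = True

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        cds_len = sum(e - s for s, e in self.cds_segments)
        if cds_len == 0 or cds_len % 3 != 0:
            self.codable = False


@dataclass
class GeneModel:
    """A protein-coding gene: strand, TSS and its transcripts.

    ``tss`` is the 0-based position of the transcription-start base, the
    5'-most exon boundary with respect to strand across all transcripts.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    transcripts: list[TranscriptModel] = field(default_factory=list)


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------


def read_population_map(path) -> dict[str, str]:
    """Read a two-column sample_id<TAB>population TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


def read_phased_vcf(path, population_map: dict[str, str]) -> dict[str, HaplotypePanel]:
    """Read a phased VCF into one :class:`HaplotypePanel` per population.

    Only biallelic SNV records whose genotypes are all phased are kept;
    multiallelic, indel and any-unphased records are dropped and counted.
    Samples absent from ``population_map`` are excluded with a warning.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        all_samples = list(vcf.header.samples)
        kept_samples = [s for s in all_samples if s in population_map]
        skipped = [s for s in all_samples if s not in population_map]
        if skipped:
            logger.warning(
                "%d VCF sample(s) absent from the population map, excluded: %s",
                len(skipped), ", ".join(skipped),
            )
        if not kept_samples:
            raise ValueError("no VCF sample appears in the population map")

        snps: list[SNPRecord] = []
        columns: list[np.ndarray] = []
        dropped = 0
        for rec in vcf:
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
            if len(alts) != 1 or len(ref) != 1 or len(alts[0]) != 1:
                dropped += 1
                continue
            alt = alts[0].upper()
            if ref not in _BASES or alt not in _BASES or ref == alt:
                dropped += 1
                continue
            col = np.empty(2 * len(kept_samples), dtype=np.int8)
            ok = True
            for i, sample in enumerate(kept_samples):
                sd = rec.samples[sample]
                gt = sd.get("GT")
                if gt is None or len(gt) != 2:
                    ok = False
                    break
                if not sd.phased and any(a is not None for a in gt):
                    ok = False
                    break
                col[2 * i] = MISSING if gt[0] is None else gt[0]
                col[2 * i + 1] = MISSING if gt[1] is None else gt[1]
            if not ok:
                dropped += 1
                continue
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            snps.append(SNPRecord(rec.chrom, rec.start, snp_id, ref, alt))
            columns.append(col)

    if dropped:
        logger.info("dropped %d VCF record(s) (multiallelic/indel/unphased)", dropped)
    if not snps:
        raise ValueError("no phased biallelic SNV records retained from VCF")

    matrix = np.stack(columns, axis=1)
    panels: dict[str, HaplotypePanel] = {}
    for pop in sorted(set(population_map[s] for s in kept_samples)):
        pop_samples = [s for s in kept_samples if population_map[s] == pop]
        rows = np.concatenate(
            [[2 * kept_samples.index(s), 2 * kept_samples.index(s) + 1]
             for s in pop_samples]
        )
        panels[pop] = HaplotypePanel(pop, pop_samples, list(snps), matrix[rows, :])
    return panels


# ---------------------------------------------------------------------------
# haplotype-table dialect
# ---------------------------------------------------------------------------

_CELL = {"0": 0, "1": 1, ".": MISSING}
_CELL_INV = {0: "0", 1: "1", MISSING: "."}


def read_haplotype_table(path, population_label: str = "POP1") -> HaplotypePanel:
    """Read the plain haplotype-matrix TSV dialect.

    Header cells are ``snp_id:chrom:pos1based:ref:alt``; each body row is
    one haplotype, with first field ``sampleID.hapIndex`` (hapIndex 0/1)
    and cells in {0, 1, .}.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        snps: list[SNPRecord] = []
        seen_ids: set[str] = set()
        for cell in header[1:]:
            snp_id, chrom, pos1, ref, alt = cell.split(":")
            if snp_id in seen_ids:
                raise ValueError(f"duplicate snp_id {snp_id!r} in header")
            seen_ids.add(snp_id)
            snps.append(SNPRecord(chrom, int(pos1) - 1, snp_id, ref, alt))

        rows: dict[str, dict[int, np.ndarray]] = {}
        order: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(snps) + 1:
                raise ValueError(f"line {lineno}: expected {len(snps) + 1} fields")
            sample, _, hap = fields[0].rpartition(".")
            if not sample or hap not in ("0", "1"):
                raise ValueError(
                    f"line {lineno}: row label must be sampleID.hapIndex with "
                    f"hapIndex in {{0,1}}, got {fields[0]!r}"
                )
            try:
                row = np.array([_CELL[c] for c in fields[1:]], dtype=np.int8)
            except KeyError as exc:
                raise ValueError(f"line {lineno}: invalid cell {exc}") from None
            haps = rows.setdefault(sample, {})
            if int(hap) in haps:
                raise ValueError(f"line {lineno}: duplicate haplotype {fields[0]!r}")
            if sample not in order:
                order.append(sample)
            haps[int(hap)] = row

    incomplete = [s for s in order if len(rows[s]) != 2]
    if incomplete:
        raise ValueError(
            f"odd haplotype count for sample(s): {', '.join(incomplete)}"
        )
    matrix = np.stack([rows[s][h] for s in order for h in (0, 1)], axis=0)
    return HaplotypePanel(population_label, order, snps, matrix)


def write_haplotype_table(panel: HaplotypePanel, path) -> None:
    """Inverse of :func:`read_haplotype_table` (exact matrix round trip)."""
    with open(path, "w") as fh:
        header = ["haplotype"] + [
            f"{s.snp_id}:{s.chrom}:{s.pos + 1}:{s.ref_allele}:{s.alt_allele}"
            for s in panel.snps
        ]
        fh.write("\t".join(header) + "\n")
        for i, sample in enumerate(panel.sample_ids):
            for h in (0, 1):
                cells = [_CELL_INV[int(v)] for v in panel.alleles[2 * i + h, :]]
                fh.write("\t".join([f"{sample}.{h}"] + cells) + "\n")


# ---------------------------------------------------------------------------
# hotspots (BED3)
# ---------------------------------------------------------------------------


def read_hotspots_bed(path) -> HotspotTrack:
    """Read a BED3 file of recombination hotspots (native 0-based half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: start {start} >= end {end}"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
    return HotspotTrack(by_chrom)


# ---------------------------------------------------------------------------
# gene models (GFF3 + FASTA)
# ---------------------------------------------------------------------------


def read_gene_models(gff3_path, fasta_path) -> list[GeneModel]:
    """Load gene models from GFF3 and attach spliced CDS sequences.

    GFF3 1-based closed coordinates become 0-based half-open; minus-strand
    CDS sequences are reverse-complemented into reading-frame order.
    Transcripts whose CDS length is not divisible by 3 are flagged
    non-codable (their intervals remain usable for feature placement).
    """
    import gffutils
    import pyfaidx

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = pyfaidx.Fasta(str(fasta_path))
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
            )
            cds = sorted(
                (c.start - 1, c.end) for c in db.children(t, featuretype="CDS")
            )
            seq = "".join(
                str(fasta[g.seqid][s:e]).upper() for s, e in cds
            )
            if g.strand == "-":
                seq = reverse_complement(seq)
            tm = TranscriptModel(t.id, g.strand, exons, cds, cds_sequence=seq)
            if cds and not tm.codable:
                logger.warning(
                    "transcript %s: CDS length %d not divisible by 3; "
                    "flagged non-codable", t.id, len(seq),
                )
            transcripts.append(tm)
        if not transcripts:
            continue
        if g.strand == "-":
            tss = max(e for t in transcripts for _, e in t.exons) - 1
        else:
            tss = min(s for t in transcripts for s, _ in t.exons)
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(GeneModel(g.id, name, g.seqid, g.strand, tss, transcripts))
    return genes


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

PAIRS_COLUMNS = [
    "population", "snp1_id", "chrom1", "pos1", "snp2_id", "chrom2", "pos2",
    "r2", "d_prime", "d", "n_haplotypes", "separation",
    "gene1", "feature1", "coding_effect1", "gene2", "feature2", "coding_effect2",
]

INTERACTIONS_COLUMNS = [
    "gene1", "gene2", "category", "coding_subtype", "population",
    "support_count", "supporting_snp_pairs", "known_evidence",
]


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _annotation_cells(ann) -> tuple[str, str, str]:
    if ann is None:
        return "", "", ""
    feature = ann.feature
    if feature == "UTR" and ann.utr_side is not None:
        feature = f"UTR{ann.utr_side}"
    effect = ann.coding_effect or ""
    return ann.gene_id, feature, effect


def write_pairs_tsv(pairs, path, annotations=None) -> None:
    """Write LRLD-SNP pairs, one row per (pair x annotation combination).

    ``annotations`` maps snp_id to a list of feature annotations; a SNP
    mapping to two overlapping genes therefore yields two rows for its
    pair (duplicate-record semantics).  With no annotations a single row
    per pair is written with empty gene columns.
    """
    annotations = annotations or {}
    rows = []
    for p in pairs:
        anns1 = annotations.get(p.snp1.snp_id) or [None]
        anns2 = annotations.get(p.snp2.snp_id) or [None]
        for a1 in anns1:
            for a2 in anns2:
                g1, f1, e1 = _annotation_cells(a1)
                g2, f2, e2 = _annotation_cells(a2)
                rows.append((
                    p.population_label, p.snp1.snp_id, p.snp1.chrom, p.snp1.pos,
                    p.snp2.snp_id, p.snp2.chrom, p.snp2.pos,
                    _fmt(p.stats.r2), _fmt(p.stats.d_prime), _fmt(p.stats.d),
                    p.stats.n_used, p.separation,
                    g1, f1, e1, g2, f2, e2,
                ))
    rows.sort(key=lambda r: (r[2], r[3], r[5], r[6], r[1], r[4],
                             r[12], r[13], r[15], r[16], r[0]))
    with open(path, "w") as fh:
        fh.write("\t".join(PAIRS_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


def write_interactions_tsv(ldgis, path) -> None:
    """Write aggregated gene interactions, one row per
    (gene pair x category x subtype x population)."""
    rows = []
    for g in ldgis:
        rows.append((
            g.gene1, g.gene2, g.category, g.coding_subtype, g.population_label,
            g.support_count, ";".join(sorted(g.supporting_pairs)),
            ",".join(sorted(g.evidence_flags)),
        ))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3], r[4]))
    with open(path, "w") as fh:
        fh.write("\t".join(INTERACTIONS_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


def read_pairs_tsv(path):
    """Read a pairs TSV back into a pandas DataFrame (ids kept as strings)."""
    import pandas as pd

    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_filter=False
    )
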