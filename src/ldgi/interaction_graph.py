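"""Aggregation of annotated LRLD-SNP pairs into gene interactions (LDGIs).

Two distinct genes connected by at least one long-range strong-LD SNP
pair form an LD-based gene interaction.  Each interaction is categorized
by the features its SNPs occupy — PROMOTER-PROMOTER, PROMOTER-CDS,
PROMOTER-UTR, CDS-CDS, CDS-UTR or UTR-UTR (5' and 3' UTRs collapse to
UTR) — and CDS sides carry their synonymous/nonsynonymous effect into a
coding subtype.  Interactions absent from every supplied evidence list
are "potentially uncharacterized".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .feature_annotation import CDS, NONSYNONYMOUS, PROMOTER, UTR, FeatureAnnotation
from .lrld_scan import LRLDPair

logger = logging.getLogger("ldgi")

CATEGORIES = (
    "PROMOTER-PROMOTER", "PROMOTER-CDS", "PROMOTER-UTR",
    "CDS-CDS", "CDS-UTR", "UTR-UTR",
)
CDS_CDS_SUBTYPES = ("NONSYN-NONSYN", "NONSYN-SYN", "SYN-SYN")

KNOWN_PPI = "KNOWN_PPI"
KNOWN_COEXPRESSION = "KNOWN_COEXPRESSION"
TRAIT_LINKED = "TRAIT_LINKED"

_FEATURE_RANK = {PROMOTER: 0, CDS: 1, UTR: 2}
_EFFECT_ABBREV = {NONSYNONYMOUS: "NONSYN", "SYNONYMOUS": "SYN"}


@dataclass(frozen=True)
class GeneInteraction:
    """One aggregated LDGI record for one population."""

    gene1: str
    gene2: str
    category: str
    coding_subtype: str
    population_label: str
    supporting_pairs: tuple[str, ...]
    evidence_flags: frozenset[str] = frozenset()

    @property
    def support_count(self) -> int:
        return len(self.supporting_pairs)


@dataclass
class BuildCounters:
    contributions: int = 0
    self_pairs: int = 0
    unannotated_pairs: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _collapse_feature(feature: str) -> str:
    return UTR if feature.startswith(UTR) else feature


def categorize_features(f1: str, e1: str | None,
                        f2: str, e2: str | None) -> tuple[str, str]:
    """Category and coding subtype from two (feature, coding effect) sides.

    Features are rendered in canonical element order PROMOTER < CDS < UTR.
    Both sides CDS: subtype is the unordered effect pair (NONSYN-NONSYN,
    NONSYN-SYN or SYN-SYN).  One CDS side: the single effect is recorded
    as NONSYN-NA / SYN-NA.  No CDS side: NA.
    """
    a, b = _collapse_feature(f1), _collapse_feature(f2)
    sides = sorted(((a, e1), (b, e2)), key=lambda s: _FEATURE_RANK[s[0]])
    category = f"{sides[0][0]}-{sides[1][0]}"
    effects = [_EFFECT_ABBREV.get(e or "", "NA") for f, e in sides if f == CDS]
    if len(effects) == 2:
        subtype = "-".join(sorted(effects))  # NONSYN < NA < SYN lexically
    elif len(effects) == 1:
        subtype = f"{effects[0]}-NA"
    else:
        subtype = "NA"
    return category, subtype


def categorize_pair(ann1: FeatureAnnotation,
                    ann2: FeatureAnnotation) -> tuple[str, str]:
    """Category and subtype for one annotation combination of a SNP pair."""
    return categorize_features(
        ann1.feature, ann1.coding_effect, ann2.feature, ann2.coding_effect
    )


def _accumulate(contributions, counters: BuildCounters) -> list[GeneInteraction]:
    """Aggregate (pop, pair_id, gene/feature sides) contributions.

    The aggregation key is (gene pair, category, subtype, population);
    support counts distinct SNP pairs.
    """
    acc: dict[tuple, set[str]] = {}
    for pop, pair_id, g1, f1, e1, g2, f2, e2 in contributions:
        if g1 == g2:
            counters.self_pairs += 1
            continue
        category, subtype = categorize_features(f1, e1, f2, e2)
        ga, gb = sorted((g1, g2))
        counters.contributions += 1
        acc.setdefault((ga, gb, category, subtype, pop), set()).add(pair_id)
    out = [
        GeneInteraction(ga, gb, cat, sub, pop, tuple(sorted(pair_ids)))
        for (ga, gb, cat, sub, pop), pair_ids in acc.items()
    ]
    out.sort(key=lambda g: (g.gene1, g.gene2, g.category,
                            g.coding_subtype, g.population_label))
    return out


def build_interactions(
    pairs: list[LRLDPair],
    annotations: dict[str, list[FeatureAnnotation]],
) -> tuple[list[GeneInteraction], BuildCounters]:
    """Cross annotated LRLD-SNP pairs into aggregated gene interactions.

    For each pair, every combination of (annotation of snp1) x
    (annotation of snp2) with distinct genes contributes; both-SNPs-in-
    one-gene combinations are dropped with a counter (the pair-level
    record keeps that information), and unannotated pairs contribute
    nothing.
    """
    counters = BuildCounters()
    contributions = []
    for p in pairs:
        anns1 = annotations.get(p.snp1.snp_id, [])
        anns2 = annotations.get(p.snp2.snp_id, [])
        if not anns1 or not anns2:
            counters.unannotated_pairs += 1
            continue
        for a1 in anns1:
            for a2 in anns2:
                contributions.append((
                    p.population_label, p.pair_id,
                    a1.gene_id, a1.feature, a1.coding_effect,
                    a2.gene_id, a2.feature, a2.coding_effect,
                ))
    return _accumulate(contributions, counters), counters


def build_interactions_from_table(df) -> tuple[list[GeneInteraction], BuildCounters]:
    """Build LDGIs from an annotated pairs table (as written by
    :func:`ldgi.io_formats.write_pairs_tsv`)."""
    counters = BuildCounters()
    contributions = []
    seen_unannotated = set()
    for row in df.itertuples(index=False):
        pair_id = f"{row.snp1_id}|{row.snp2_id}"
        if not row.gene1 or not row.gene2:
            seen_unannotated.add((row.population, pair_id))
            continue
        contributions.append((
            row.population, pair_id,
            row.gene1, row.feature1, row.coding_effect1 or None,
            row.gene2, row.feature2, row.coding_effect2 or None,
        ))
    counters.unannotated_pairs = len(seen_unannotated)
    return _accumulate(contributions, counters), counters


# ---------------------------------------------------------------------------
# external evidence overlay
# ---------------------------------------------------------------------------


def read_gene_pairs_tsv(path) -> set[frozenset]:
    """Read a two-column gene-pair TSV into a set of unordered pairs."""
    out: set[frozenset] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            out.add(frozenset(fields[:2]))
    return out


def read_snp_traits_tsv(path) -> dict[str, list[str]]:
    """Read a snp_id<TAB>trait TSV."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            out.setdefault(fields[0], []).append(fields[1])
    return out


def overlay_evidence(
    ldgis: list[GeneInteraction],
    ppi_pairs: set[frozenset] | None = None,
    coexpression_pairs: set[frozenset] | None = None,
    snp_traits: dict[str, list[str]] | None = None,
) -> tuple[list[GeneInteraction], dict[str, int]]:
    """Flag LDGIs found in external gene-pair lists or SNP-trait tables.

    Matching is on unordered gene pairs; TRAIT_LINKED is set when any
    supporting SNP has a trait entry.  Evidence rows naming genes/SNPs
    outside the LDGI set never match and are counted as unknown.  The
    overlay is idempotent: flags are recomputed, not appended.
    """
    ppi_pairs = ppi_pairs or set()
    coexpression_pairs = coexpression_pairs or set()
    snp_traits = snp_traits or {}

    genes = {g for x in ldgis for g in (x.gene1, x.gene2)}
    snps = {
        s for x in ldgis for pid in x.supporting_pairs for s in pid.split("|")
    }
    counters = {
        "unknown_evidence_genes": sum(
            1 for pair in (ppi_pairs | coexpression_pairs)
            if not (pair & genes)
        ),
        "unknown_trait_snps": sum(1 for s in snp_traits if s not in snps),
    }

    out: list[GeneInteraction] = []
    for x in ldgis:
        flags = set()
        key = frozenset((x.gene1, x.gene2))
        if key in ppi_pairs:
            flags.add(KNOWN_PPI)
        if key in coexpression_pairs:
            flags.add(KNOWN_COEXPRESSION)
        support_snps = {s for pid in x.supporting_pairs for s in pid.split("|")}
        if any(s in snp_traits for s in support_snps):
            flags.add(TRAIT_LINKED)
        out.append(GeneInteraction(
            x.gene1, x.gene2, x.category, x.coding_subtype,
            x.population_label, x.supporting_pairs, frozenset(flags),
        ))
    return out, counters


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (0-based half-open)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(
            f"malformed region {region!r}; expected chrom:start-end"
        )
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start >= end:
        raise ValueError(f"region {region!r} is empty")
    return chrom, start, end


def query_pairs(pairs: list[LRLDPair], snp_id: str | None = None,
                region: str | None = None,
                populations: set[str] | None = None,
                r2_min: float | None = None) -> list[LRLDPair]:
    """Composable filter over LRLD-SNP pairs (intersection semantics)."""
    out = pairs
    if snp_id is not None:
        out = [p for p in out
               if snp_id in (p.snp1.snp_id, p.snp2.snp_id)]
    if region is not None:
        chrom, start, end = parse_region(region)
        out = [
            p for p in out
            if any(s.chrom == chrom and start <= s.pos < end
                   for s in (p.snp1, p.snp2))
        ]
    if populations is not None:
        out = [p for p in out if p.population_label in populations]
    if r2_min is not None:
        from .lrld_scan import effective_threshold

        thr = effective_threshold(r2_min)
        out = [p for p in out if p.stats.r2 >= thr]
    return list(out)


def query_interactions(ldgis: list[GeneInteraction],
                       gene_id: str | None = None,
                       categories: set[str] | None = None,
                       populations: set[str] | None = None,
                       ) -> list[GeneInteraction]:
    """Composable filter over gene interactions (intersection semantics)."""
    out = ldgis
    if gene_id is not None:
        out = [g for g in out if gene_id in (g.gene1, g.gene2)]
    if categories is not None:
        out = [g for g in out if g.category in categories]
    if populations is not None:
        out = [g for g in out if g.population_label in populations]
    return list(out)
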