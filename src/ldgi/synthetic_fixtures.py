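"""Seeded simulation of phased panels with planted long-range LD structure.

The generator emits everything the pipeline reads — a phased haplotype
table, a hotspot BED, strand-aware multi-exon gene models as GFF3 plus a
genome FASTA — together with a truth manifest describing the planted
LRLD-SNP pairs and the gene-interaction table the pipeline is expected
to reproduce.

Planting inverts the r2 formula analytically: given target r2 and the
major-allele frequencies, the positive-D root fixes the joint haplotype
frequency P_AB, the four haplotype probabilities are rounded to integer
counts summing to the panel size, and the achieved r2 is re-measured on
the realized columns.  Infeasible targets (e.g. r2 = 1 with unequal
allele frequencies) raise an error stating the maximum attainable r2
rather than drifting silently.

The default configuration plants 25 cross-chromosome strong-LD pairs
(achieved r2 >= 0.9), four cross-hotspot strong-LD pairs, ten same-block
complete-LD decoys (high LD but not long range), six cross-hotspot
weak-LD decoys (long range but below threshold), and independent
background SNPs, in a panel of 100 haplotypes (50 individuals).  It is
statistical structure only: no coalescent realism, no recombination-rate
maps, no demography.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import ld_core
from .io_formats import (
    GeneModel,
    HaplotypePanel,
    HotspotTrack,
    SNPRecord,
    TranscriptModel,
    write_haplotype_table,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Feature prescriptions a planted SNP can carry.
FEATURE_CHOICES = ("PROMOTER", "UTR5", "UTR3", "CDS_SYN", "CDS_NONSYN")

CROSS_CHROM = "CROSS_CHROM"
CROSS_HOTSPOT = "CROSS_HOTSPOT"
SAME_BLOCK_DECOY = "SAME_BLOCK_DECOY"
LOW_LD_DECOY = "LOW_LD_DECOY"


class InfeasibleTargetError(ValueError):
    """Requested r2 cannot be realized at the given allele frequencies."""

    def __init__(self, target_r2, max_r2):
        self.target_r2 = target_r2
        self.max_r2 = max_r2
        super().__init__(
            f"target r2 = {target_r2} infeasible at these frequencies; "
            f"maximum attainable r2 = {max_r2:.6g}"
        )


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _largest_remainder(probs, n: int) -> list[int]:
    quotas = [p * n for p in probs]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(
        range(len(probs)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


def plant_pair(n_haplotypes: int, target_r2: float, p_a: float, p_b: float,
               rng: np.random.Generator):
    """Construct two allele columns realizing a target r2.

    ``p_a``/``p_b`` are the frequencies of the 0-coded allele at the two
    loci.  Returns ``(col1, col2, achieved_r2)`` with the achieved value
    measured on the realized integer counts.  Row order is shuffled with
    ``rng``; the joint haplotype distribution is what carries the LD, so
    the shuffle changes nothing statistically but decouples planted pairs
    from each other positionally.
    """
    if n_haplotypes % 2 != 0 or n_haplotypes < 4:
        raise ValueError("n_haplotypes must be even and >= 4")
    if not (0.0 <= target_r2 <= 1.0):
        raise ValueError("target_r2 must be in [0, 1]")
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("allele frequencies must be in (0, 1)")
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    d = math.sqrt(target_r2 * denom)  # positive-D root
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    if d > d_max + 1e-12:
        raise InfeasibleTargetError(target_r2, (d_max * d_max) / denom)
    probs = [
        p_a * p_b + d,              # 0,0
        p_a * (1 - p_b) - d,        # 0,1
        (1 - p_a) * p_b - d,        # 1,0
        (1 - p_a) * (1 - p_b) + d,  # 1,1
    ]
    probs = [max(0.0, p) for p in probs]
    counts = _largest_remainder(probs, n_haplotypes)
    rows = []
    for (a, b), c in zip(((0, 0), (0, 1), (1, 0), (1, 1)), counts):
        rows.extend([(a, b)] * c)
    arr = np.array(rows, dtype=np.int8)
    arr = arr[rng.permutation(n_haplotypes), :]
    col1, col2 = arr[:, 0].copy(), arr[:, 1].copy()
    achieved = ld_core.compute_ld(col1, col2, min_haplotypes=2).r2
    return col1, col2, achieved


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSide:
    """One locus of a planted pair, with an optional feature prescription."""

    chrom: str
    pos: int
    feature: str | None = None  # one of FEATURE_CHOICES, or None (intergenic)
    strand: str = "+"
    anchor: int | None = None  # explicit gene anchor (shared-gene cases)
    overlap_gene: bool = False  # add an overlapping second gene over this SNP


@dataclass(frozen=True)
class PlantedPairSpec:
    name: str
    side1: PlantedSide
    side2: PlantedSide
    target_r2: float
    kind: str
    p_a: float = 0.5
    p_b: float = 0.5

    @property
    def long_range(self) -> bool:
        return self.kind in (CROSS_CHROM, CROSS_HOTSPOT)


@dataclass(frozen=True)
class SimulationConfig:
    chromosomes: tuple[tuple[str, int], ...]
    hotspots: dict[str, tuple[tuple[int, int], ...]]
    planted: tuple[PlantedPairSpec, ...]
    background_regions: dict[str, tuple[int, int]]
    background_per_chrom: int = 20
    n_haplotypes: int = 100
    population_label: str = "SIM1"
    r2_threshold: float = 0.8  # threshold the expected tables are stated at


def default_config() -> SimulationConfig:
    """The standard simulated study: see module docstring for the census."""
    planted: list[PlantedPairSpec] = []
    combos = list(itertools.combinations_with_replacement(FEATURE_CHOICES, 2))

    # 25 cross-chromosome strong-LD pairs covering every feature combination.
    shared_anchor = 142_000
    for i in range(25):
        base = 3000 + 6000 * i
        s1_strand = "+" if i % 2 == 0 else "-"
        s2_strand = "-" if i % 2 == 0 else "+"
        target = 1.0 if i % 2 == 1 else 0.9216
        if i >= 23:
            # Two pairs share one promoter gene per side, so the same gene
            # pair aggregates with support_count 2.
            off = 600 if i == 23 else 1200
            side1 = PlantedSide("chr1", shared_anchor - off, "PROMOTER",
                                "+", anchor=shared_anchor)
            side2 = PlantedSide("chr2", shared_anchor - off, "PROMOTER",
                                "+", anchor=shared_anchor)
        else:
            f1, f2 = combos[i % len(combos)]
            side1 = PlantedSide("chr1", base, f1, s1_strand)
            side2 = PlantedSide("chr2", base, f2, s2_strand,
                                overlap_gene=(i == 3))
        planted.append(PlantedPairSpec(f"cc{i}", side1, side2, target,
                                       CROSS_CHROM))

    # Four same-chromosome pairs separated by a recombination hotspot.
    ch_feats = [("CDS_SYN", "CDS_SYN"), ("CDS_NONSYN", "CDS_NONSYN"),
                ("PROMOTER", "CDS_NONSYN"), ("UTR5", "UTR3")]
    for i, (f1, f2) in enumerate(ch_feats):
        planted.append(PlantedPairSpec(
            f"ch{i}",
            PlantedSide("chr3", 3000 + 6000 * i, f1, "+" if i % 2 else "-"),
            PlantedSide("chr3", 33_000 + 6000 * i, f2, "-" if i % 2 else "+"),
            0.9216, CROSS_HOTSPOT,
        ))

    # Ten same-block complete-LD decoys (must never be emitted).
    for i in range(10):
        p = 62_000 + 1000 * i
        planted.append(PlantedPairSpec(
            f"sb{i}", PlantedSide("chr3", p), PlantedSide("chr3", p + 500),
            1.0, SAME_BLOCK_DECOY,
        ))

    # Six cross-hotspot weak-LD decoys (long range, below threshold).
    for i in range(6):
        planted.append(PlantedPairSpec(
            f"ll{i}", PlantedSide("chr3", 25_000 + 250 * i),
            PlantedSide("chr3", 55_000 + 250 * i),
            0.16, LOW_LD_DECOY,
        ))

    return SimulationConfig(
        chromosomes=(("chr1", 200_000), ("chr2", 200_000), ("chr3", 100_000)),
        hotspots={"chr3": ((30_000, 30_500), (60_000, 60_500))},
        planted=tuple(planted),
        background_regions={
            "chr1": (155_000, 198_000),
            "chr2": (155_000, 198_000),
            "chr3": (78_000, 98_000),
        },
        background_per_chrom=20,
        n_haplotypes=100,
    )


def small_scan_config() -> SimulationConfig:
    """A compact panel (<= 60 SNPs, no gene features) for scan-level checks."""
    planted = [
        PlantedPairSpec("cc0", PlantedSide("chrA", 5000),
                        PlantedSide("chrB", 5000), 0.9216, CROSS_CHROM),
        PlantedPairSpec("cc1", PlantedSide("chrA", 8000),
                        PlantedSide("chrB", 8000), 1.0, CROSS_CHROM),
        PlantedPairSpec("ch0", PlantedSide("chrA", 12_000),
                        PlantedSide("chrA", 25_000), 0.9216, CROSS_HOTSPOT),
        PlantedPairSpec("sb0", PlantedSide("chrA", 30_000),
                        PlantedSide("chrA", 30_800), 1.0, SAME_BLOCK_DECOY),
        PlantedPairSpec("sb1", PlantedSide("chrB", 12_000),
                        PlantedSide("chrB", 13_000), 1.0, SAME_BLOCK_DECOY),
        PlantedPairSpec("ll0", PlantedSide("chrA", 6000),
                        PlantedSide("chrA", 26_000), 0.16, LOW_LD_DECOY),
    ]
    return SimulationConfig(
        chromosomes=(("chrA", 50_000), ("chrB", 50_000)),
        hotspots={"chrA": ((20_000, 20_500),)},
        planted=tuple(planted),
        background_regions={"chrA": (35_000, 49_000), "chrB": (30_000, 49_000)},
        background_per_chrom=15,
        n_haplotypes=60,
    )


# ---------------------------------------------------------------------------
# deterministic SNP / gene planning
# ---------------------------------------------------------------------------

# (ref, alt) genomic alleles per (feature, strand); CDS prescriptions are
# chosen so the planted substitution realizes the prescribed effect
# (CTA->CTG Leu/Leu for synonymous, CAT->GAT His/Asp for nonsynonymous).
_ALLELES = {
    ("CDS_SYN", "+"): ("A", "G"),
    ("CDS_NONSYN", "+"): ("C", "G"),
    ("CDS_SYN", "-"): ("T", "C"),
    ("CDS_NONSYN", "-"): ("G", "C"),
}


def _side_alleles(side: PlantedSide) -> tuple[str, str]:
    return _ALLELES.get((side.feature, side.strand), ("A", "G"))


# SNP offset from the gene anchor per (feature, strand); the anchor is the
# 5'-most genomic coordinate of the gene body on '+', the body start on '-'.
_ANCHOR_OFFSET = {
    ("PROMOTER", "+"): -1000, ("UTR5", "+"): 10, ("UTR3", "+"): 140,
    ("CDS_SYN", "+"): 35, ("CDS_NONSYN", "+"): 36,
    ("PROMOTER", "-"): 1159, ("UTR5", "-"): 145, ("UTR3", "-"): 15,
    ("CDS_SYN", "-"): 124, ("CDS_NONSYN", "-"): 123,
}


def _side_anchor(side: PlantedSide) -> int:
    if side.anchor is not None:
        return side.anchor
    return side.pos - _ANCHOR_OFFSET[(side.feature, side.strand)]


@dataclass
class _GeneSpec:
    gene_id: str
    chrom: str
    anchor: int
    strand: str
    overlap: bool = False  # overlapping companion gene, UTR3 template


def _gene_plan(config: SimulationConfig):
    """Deterministic gene layout and per-SNP expected placements.

    Returns ``(gene_specs, placements)`` where placements maps planted
    snp_id -> list of expected annotation dicts.
    """
    gene_specs: dict[str, _GeneSpec] = {}
    placements: dict[str, list[dict]] = {}
    for spec in config.planted:
        for idx, side in ((1, spec.side1), (2, spec.side2)):
            snp_id = f"{spec.name}_{idx}"
            if side.feature is None:
                continue
            anchor = _side_anchor(side)
            tag = "P" if side.strand == "+" else "M"
            gene_id = f"GENE_{side.chrom}_{anchor}_{tag}"
            gene_specs.setdefault(
                gene_id, _GeneSpec(gene_id, side.chrom, anchor, side.strand)
            )
            feature = "CDS" if side.feature.startswith("CDS") else side.feature
            effect = None
            if side.feature == "CDS_SYN":
                effect = "SYNONYMOUS"
            elif side.feature == "CDS_NONSYN":
                effect = "NONSYNONYMOUS"
            entry = [{
                "gene_id": gene_id,
                "transcript_id": "" if feature == "PROMOTER" else f"{gene_id}.t1",
                "feature": feature,
                "coding_effect": effect,
            }]
            if side.overlap_gene:
                if side.feature != "CDS_SYN" or side.strand != "+":
                    raise ValueError(
                        "overlap_gene is only supported on a '+'-strand "
                        "CDS_SYN side"
                    )
                ov_id = f"{gene_id}.ov"
                gene_specs.setdefault(
                    ov_id, _GeneSpec(ov_id, side.chrom, anchor, "+", overlap=True)
                )
                entry.append({
                    "gene_id": ov_id,
                    "transcript_id": f"{ov_id}.t1",
                    "feature": "UTR3",
                    "coding_effect": None,
                })
            placements[snp_id] = entry
    return gene_specs, placements


def _snp_plan(config: SimulationConfig):
    """Planted SNP records in config order (background SNPs are seeded)."""
    records = {}
    for spec in config.planted:
        for idx, side in ((1, spec.side1), (2, spec.side2)):
            snp_id = f"{spec.name}_{idx}"
            ref, alt = _side_alleles(side)
            records[snp_id] = SNPRecord(side.chrom, side.pos, snp_id, ref, alt)
    return records


def _background_plan(config: SimulationConfig, seed: int):
    """Seeded background SNP records (positions and alleles)."""
    rng = np.random.default_rng([seed, 2])
    bases = "ACGT"
    records = []
    for chrom, _ in config.chromosomes:
        region = config.background_regions.get(chrom)
        if region is None or config.background_per_chrom == 0:
            continue
        lo, hi = region
        positions = np.sort(rng.choice(
            np.arange(lo, hi), size=config.background_per_chrom, replace=False
        ))
        for j, pos in enumerate(positions):
            ref = bases[rng.integers(0, 4)]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            records.append(
                SNPRecord(chrom, int(pos), f"bg_{chrom}_{j}", ref, alt)
            )
    return records


# ---------------------------------------------------------------------------
# truth manifest
# ---------------------------------------------------------------------------


@dataclass
class TruthManifest:
    """Ground truth for one simulated bundle."""

    population_label: str
    n_haplotypes: int
    seed: int
    r2_threshold: float
    planted_pairs: list[dict]
    placements: dict[str, list[dict]]
    expected_pair_ids: list[str]
    expected_interactions: list[dict]

    def to_dict(self) -> dict:
        return {
            "population_label": self.population_label,
            "n_haplotypes": self.n_haplotypes,
            "seed": self.seed,
            "r2_threshold": self.r2_threshold,
            "planted_pairs": self.planted_pairs,
            "placements": self.placements,
            "expected_pair_ids": self.expected_pair_ids,
            "expected_interactions": self.expected_interactions,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(**{k: d[k] for k in (
            "population_label", "n_haplotypes", "seed", "r2_threshold",
            "planted_pairs", "placements", "expected_pair_ids",
            "expected_interactions",
        )})


def _expected_interactions(config, placements, emitted):
    """Expected aggregated LDGI table, derived from the prescriptions only.

    This is the generator's own bookkeeping (feature combination in
    canonical PROMOTER < CDS < UTR order, CDS effects folded into the
    subtype) so pipeline output can be checked against it.
    """
    rank = {"PROMOTER": 0, "CDS": 1, "UTR": 2}
    abbrev = {"SYNONYMOUS": "SYN", "NONSYNONYMOUS": "NONSYN"}
    acc: dict[tuple, set] = {}
    for spec in config.planted:
        pid = emitted.get(spec.name)
        if pid is None:
            continue
        for p1 in placements.get(f"{spec.name}_1", []):
            for p2 in placements.get(f"{spec.name}_2", []):
                if p1["gene_id"] == p2["gene_id"]:
                    continue
                sides = []
                for p in (p1, p2):
                    f = p["feature"]
                    f = "UTR" if f.startswith("UTR") else f
                    sides.append((f, abbrev.get(p["coding_effect"], "NA")))
                sides.sort(key=lambda s: rank[s[0]])
                category = f"{sides[0][0]}-{sides[1][0]}"
                effects = sorted(e for f, e in sides if f == "CDS")
                if len(effects) == 2:
                    subtype = "-".join(effects)
                elif len(effects) == 1:
                    subtype = f"{effects[0]}-NA"
                else:
                    subtype = "NA"
                g1, g2 = sorted((p1["gene_id"], p2["gene_id"]))
                acc.setdefault(
                    (g1, g2, category, subtype, config.population_label), set()
                ).add(pid)
    out = [
        {
            "gene1": g1, "gene2": g2, "category": cat, "coding_subtype": sub,
            "population": pop, "support_count": len(pids),
            "supporting_snp_pairs": sorted(pids),
        }
        for (g1, g2, cat, sub, pop), pids in sorted(acc.items())
    ]
    return out


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------


def simulate_panel(config: SimulationConfig, seed: int):
    """Simulate the phased panel, hotspot track and truth manifest.

    Background columns are drawn independently (expected background r2
    near zero at the default 100 haplotypes); planted columns come from
    :func:`plant_pair`.  Fully reproducible per seed.
    """
    snp_records = _snp_plan(config)
    background = _background_plan(config, seed)
    all_positions = [(r.chrom, r.pos) for r in snp_records.values()] + [
        (r.chrom, r.pos) for r in background
    ]
    if len(set(all_positions)) != len(all_positions):
        raise ValueError("planted/background SNP positions collide")

    rng = np.random.default_rng([seed, 0])
    n = config.n_haplotypes
    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    planted_pairs: list[dict] = []
    emitted: dict[str, str] = {}
    thr = config.r2_threshold

    for spec in config.planted:
        col1, col2, achieved = plant_pair(n, spec.target_r2, spec.p_a,
                                          spec.p_b, rng)
        r1 = snp_records[f"{spec.name}_1"]
        r2_ = snp_records[f"{spec.name}_2"]
        snps.extend([r1, r2_])
        columns.extend([col1, col2])
        first, second = sorted([r1, r2_])
        pair_id = f"{first.snp_id}|{second.snp_id}"
        planted_pairs.append({
            "name": spec.name,
            "snp1_id": first.snp_id,
            "snp2_id": second.snp_id,
            "kind": spec.kind,
            "target_r2": spec.target_r2,
            "achieved_r2": achieved,
            "long_range": spec.long_range,
        })
        if spec.long_range and achieved >= thr:
            emitted[spec.name] = pair_id

    for rec in background:
        for _ in range(100):
            maf = rng.uniform(0.15, 0.5)
            col = (rng.random(n) < maf).astype(np.int8)
            if 0 < int(col.sum()) < n:
                break
        else:  # pragma: no cover - p(failure) vanishes at n >= 40
            raise RuntimeError("could not draw a polymorphic background column")
        snps.append(rec)
        columns.append(col)

    n_ind = n // 2
    sample_ids = [f"S{i:03d}" for i in range(n_ind)]
    panel = HaplotypePanel(
        config.population_label, sample_ids, snps,
        np.stack(columns, axis=1),
    )
    track = HotspotTrack({c: list(v) for c, v in config.hotspots.items()})

    _, placements = _gene_plan(config)
    manifest = TruthManifest(
        population_label=config.population_label,
        n_haplotypes=n,
        seed=seed,
        r2_threshold=thr,
        planted_pairs=planted_pairs,
        placements=placements,
        expected_pair_ids=sorted(emitted.values()),
        expected_interactions=_expected_interactions(config, placements, emitted),
    )
    return panel, track, manifest


# ---------------------------------------------------------------------------
# gene landscape simulation
# ---------------------------------------------------------------------------


def _write_base(genome: np.ndarray, pos: int, base: str) -> None:
    genome[pos] = base


def _build_plus_gene(spec: _GeneSpec, genome) -> GeneModel:
    g = spec.anchor
    exons = [(g, g + 60), (g + 100, g + 160)]
    cds = [(g + 30, g + 60), (g + 100, g + 130)]
    for i, b in enumerate("ATG"):
        _write_base(genome, g + 30 + i, b)
    tr = TranscriptModel(f"{spec.gene_id}.t1", "+", exons, cds)
    return GeneModel(spec.gene_id, spec.gene_id, spec.chrom, "+", g, [tr])


def _build_minus_gene(spec: _GeneSpec, genome) -> GeneModel:
    g = spec.anchor
    exons = [(g, g + 60), (g + 100, g + 160)]
    cds = [(g + 30, g + 60), (g + 100, g + 130)]
    # start codon ATG at transcript CDS offsets 0..2 <-> genomic g+129..g+127
    _write_base(genome, g + 129, _COMP["A"])
    _write_base(genome, g + 128, _COMP["T"])
    _write_base(genome, g + 127, _COMP["G"])
    tr = TranscriptModel(f"{spec.gene_id}.t1", "-", exons, cds)
    return GeneModel(spec.gene_id, spec.gene_id, spec.chrom, "-", g + 159, [tr])


def _build_overlap_gene(spec: _GeneSpec, genome) -> GeneModel:
    """Companion '+'-strand gene whose 3'UTR covers the host SNP position."""
    g = spec.anchor
    exons = [(g - 400, g - 340), (g + 30, g + 40)]
    cds = [(g - 370, g - 340)]
    for i, b in enumerate("ATG"):
        _write_base(genome, g - 370 + i, b)
    tr = TranscriptModel(f"{spec.gene_id}.t1", "+", exons, cds)
    return GeneModel(spec.gene_id, spec.gene_id, spec.chrom, "+", g - 400, [tr])


def _write_codon_bases(side: PlantedSide, anchor: int, genome) -> None:
    """Fix the planted codon's non-SNP bases so the prescribed effect holds."""
    g = anchor
    if side.strand == "+":
        if side.feature == "CDS_SYN":  # codon CTx at CDS offsets 3..5
            _write_base(genome, g + 33, "C")
            _write_base(genome, g + 34, "T")
        elif side.feature == "CDS_NONSYN":  # codon xAT at CDS offsets 6..8
            _write_base(genome, g + 37, "A")
            _write_base(genome, g + 38, "T")
    else:
        if side.feature == "CDS_SYN":  # transcript codon CTx <-> g+126..g+124
            _write_base(genome, g + 126, _COMP["C"])
            _write_base(genome, g + 125, _COMP["T"])
        elif side.feature == "CDS_NONSYN":  # transcript codon xAT <-> g+123..g+121
            _write_base(genome, g + 122, _COMP["A"])
            _write_base(genome, g + 121, _COMP["T"])


def simulate_gene_landscape(config: SimulationConfig, seed: int):
    """Build the genome and gene models hosting the planted SNPs.

    Returns ``(genes, genome, placements)`` where ``genome`` maps
    chromosome name to a numpy array of bases.  Every SNP's reference
    allele is written into the genome, and CDS codons are constructed so
    planted alleles realize their prescribed synonymous/nonsynonymous
    effect.
    """
    rng = np.random.default_rng([seed, 1])
    alphabet = np.array(list("ACGT"))
    genome: dict[str, np.ndarray] = {
        chrom: alphabet[rng.integers(0, 4, size=length)]
        for chrom, length in config.chromosomes
    }
    gene_specs, placements = _gene_plan(config)

    genes: list[GeneModel] = []
    for gid in sorted(gene_specs):
        spec = gene_specs[gid]
        if spec.overlap:
            genes.append(_build_overlap_gene(spec, genome[spec.chrom]))
        elif spec.strand == "+":
            genes.append(_build_plus_gene(spec, genome[spec.chrom]))
        else:
            genes.append(_build_minus_gene(spec, genome[spec.chrom]))

    snp_records = _snp_plan(config)
    for spec in config.planted:
        for idx, side in ((1, spec.side1), (2, spec.side2)):
            rec = snp_records[f"{spec.name}_{idx}"]
            if side.feature is not None:
                anchor = _side_anchor(side)
                _write_codon_bases(side, anchor, genome[side.chrom])
            _write_base(genome[side.chrom], rec.pos, rec.ref_allele)
    for rec in _background_plan(config, seed):
        _write_base(genome[rec.chrom], rec.pos, rec.ref_allele)

    # attach spliced CDS sequences now that the genome is final
    for gene in genes:
        chrom_seq = genome[gene.chrom]
        for tr in gene.transcripts:
            seq = "".join(
                "".join(chrom_seq[s:e]) for s, e in tr.cds_segments
            )
            if gene.strand == "-":
                seq = "".join(_COMP[b] for b in reversed(seq))
            tr.cds_sequence = seq
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes, genome, placements


# ---------------------------------------------------------------------------
# bundle assembly and file emission
# ---------------------------------------------------------------------------


@dataclass
class SimulatedBundle:
    panel: HaplotypePanel
    track: HotspotTrack
    genes: list[GeneModel]
    genome: dict[str, np.ndarray]
    manifest: TruthManifest
    paths: dict[str, str] = field(default_factory=dict)


def _write_fasta(genome: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_bed(track: HotspotTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            for s, e in track.intervals(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def _gff3_lines(genes: list[GeneModel]):
    yield "##gff-version 3"
    for gene in genes:
        lo = min(s for t in gene.transcripts for s, _ in t.exons)
        hi = max(e for t in gene.transcripts for _, e in t.exons)
        attrs = f"ID={gene.gene_id};Name={gene.gene_name}"
        yield (f"{gene.chrom}\tldgi_sim\tgene\t{lo + 1}\t{hi}\t.\t"
               f"{gene.strand}\t.\t{attrs}")
        for tr in gene.transcripts:
            t_lo = min(s for s, _ in tr.exons)
            t_hi = max(e for _, e in tr.exons)
            yield (f"{gene.chrom}\tldgi_sim\tmRNA\t{t_lo + 1}\t{t_hi}\t.\t"
                   f"{gene.strand}\t.\tID={tr.transcript_id};"
                   f"Parent={gene.gene_id}")
            for k, (s, e) in enumerate(tr.exons):
                yield (f"{gene.chrom}\tldgi_sim\texon\t{s + 1}\t{e}\t.\t"
                       f"{gene.strand}\t.\tID={tr.transcript_id}.e{k};"
                       f"Parent={tr.transcript_id}")
            segs = tr.cds_segments
            ordered = segs if gene.strand == "+" else list(reversed(segs))
            acc = 0
            for k, (s, e) in enumerate(ordered):
                phase = (3 - acc % 3) % 3
                acc += e - s
                yield (f"{gene.chrom}\tldgi_sim\tCDS\t{s + 1}\t{e}\t.\t"
                       f"{gene.strand}\t{phase}\tID={tr.transcript_id}.c{k};"
                       f"Parent={tr.transcript_id}")


def _write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for line in _gff3_lines(genes):
            fh.write(line + "\n")


def _write_popmap(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        for s in panel.sample_ids:
            fh.write(f"{s}\t{panel.population_label}\n")


def simulate_bundle(config: SimulationConfig, seed: int,
                    out_dir=None) -> SimulatedBundle:
    """Simulate panel + landscape and (optionally) write all input files.

    With ``out_dir`` set, writes haplotypes.tsv, popmap.tsv, hotspots.bed,
    genes.gff3, genome.fa and truth.json; identical seeds produce
    byte-identical files.
    """
    panel, track, manifest = simulate_panel(config, seed)
    genes, genome, _ = simulate_gene_landscape(config, seed)
    bundle = SimulatedBundle(panel, track, genes, genome, manifest)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "haplotypes": os.path.join(out_dir, "haplotypes.tsv"),
            "popmap": os.path.join(out_dir, "popmap.tsv"),
            "hotspots": os.path.join(out_dir, "hotspots.bed"),
            "gff3": os.path.join(out_dir, "genes.gff3"),
            "fasta": os.path.join(out_dir, "genome.fa"),
            "manifest": os.path.join(out_dir, "truth.json"),
        }
        write_haplotype_table(panel, paths["haplotypes"])
        _write_popmap(panel, paths["popmap"])
        _write_bed(track, paths["hotspots"])
        _write_gff3(genes, paths["gff3"])
        _write_fasta(genome, paths["fasta"])
        with open(paths["manifest"], "w") as fh:
            fh.write(manifest.to_json() + "\n")
        bundle.paths = paths
    return bundle
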