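"""Detection of long-range strong-LD SNP pairs (LRLD-SNP pairs).

A pair of SNPs is *long range* when the two loci are on different
chromosomes, or on the same chromosome but separated by at least one
recombination hotspot — the conservative reading being that a merged
hotspot interval must lie entirely inside the open gap between the two
positions.  Long-range pairs whose phased-haplotype r2 reaches the
configured threshold (0.8, 0.9 or 1.0; "complete" LD at 1.0 uses a
1e-9 tolerance) are emitted as LRLD-SNP pairs.

The positional filter always runs before any LD computation, so only
candidate pairs that could qualify are ever scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import ld_core
from .io_formats import HaplotypePanel, HotspotTrack, SNPRecord
from .ld_core import LDStatistics

logger = logging.getLogger("ldgi")

#: r2 thresholds offered, mirroring the adjustable strong-LD parameter.
ALLOWED_R2_MIN = (0.8, 0.9, 1.0)

#: Tolerance for the "complete LD" (r2 = 1) tier.
COMPLETE_LD_TOL = 1e-9

DIFF_CHROM = "DIFF_CHROM"


@dataclass(frozen=True)
class LRLDPair:
    """One long-range strong-LD SNP pair in one population.

    ``snp1`` precedes ``snp2`` in (chrom, pos, snp_id) order; ``separation``
    is ``DIFF_CHROM`` or ``HOTSPOTS:k`` with k >= 1.
    """

    snp1: SNPRecord
    snp2: SNPRecord
    population_label: str
    stats: LDStatistics
    separation: str

    @property
    def pair_id(self) -> str:
        return f"{self.snp1.snp_id}|{self.snp2.snp_id}"


@dataclass
class ScanCounters:
    """Bookkeeping of candidate pairs skipped during a scan."""

    candidates: int = 0
    same_block: int = 0
    monomorphic: int = 0
    low_n: int = 0
    below_threshold: int = 0
    emitted: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def hotspots_between(chrom: str, pos_lo: int, pos_hi: int,
                     track: HotspotTrack) -> int:
    """Number of merged hotspot intervals entirely inside (pos_lo, pos_hi].

    An interval [s, e) counts when ``pos_lo < s`` and ``e <= pos_hi``: a
    hotspot straddling either SNP position does not cleanly separate the
    loci and is not counted.
    """
    if pos_lo >= pos_hi:
        raise ValueError("pos_lo must be < pos_hi")
    first_inside = track.rank_start_le(chrom, pos_lo)
    last_inside = track.rank_end_le(chrom, pos_hi)
    return max(0, last_inside - first_inside)


def is_long_range(snp1: SNPRecord, snp2: SNPRecord,
                  track: HotspotTrack) -> tuple[bool, str | None]:
    """Apply the long-range criterion to one SNP pair.

    Returns ``(True, "DIFF_CHROM")`` for different chromosomes,
    ``(True, "HOTSPOTS:k")`` for same-chromosome pairs separated by k >= 1
    merged hotspots, and ``(False, None)`` otherwise (presumed same LD
    block).
    """
    if snp1 == snp2:
        raise ValueError("a SNP cannot be paired with itself")
    if snp1.chrom != snp2.chrom:
        return True, DIFF_CHROM
    lo, hi = sorted((snp1.pos, snp2.pos))
    if lo == hi:
        return False, None
    k = hotspots_between(snp1.chrom, lo, hi, track)
    if k >= 1:
        return True, f"HOTSPOTS:{k}"
    return False, None


def filter_population_size(panels: dict[str, HaplotypePanel],
                           min_individuals: int = 20) -> dict[str, HaplotypePanel]:
    """Drop populations with fewer than ``min_individuals`` individuals."""
    kept: dict[str, HaplotypePanel] = {}
    for label, panel in panels.items():
        if panel.n_individuals >= min_individuals:
            kept[label] = panel
        else:
            logger.info(
                "population %s dropped: %d individuals < %d",
                label, panel.n_individuals, min_individuals,
            )
    if not kept:
        raise ValueError(
            f"no population meets the {min_individuals}-individual floor"
        )
    return kept


def effective_threshold(r2_min: float) -> float:
    return 1.0 - COMPLETE_LD_TOL if r2_min >= 1.0 else r2_min


def scan_population(panel: HaplotypePanel, track: HotspotTrack,
                    r2_min: float = 0.8, min_haplotypes: int = 40,
                    ) -> tuple[list[LRLDPair], ScanCounters]:
    """Enumerate LRLD-SNP pairs in one population.

    Every unordered SNP pair passing :func:`is_long_range` is scored with
    :func:`ldgi.ld_core.compute_ld`; pairs at or above the threshold are
    returned in canonical (chrom, pos) order.  Monomorphic and low-data
    skips accumulate in the returned counters.
    """
    if r2_min not in ALLOWED_R2_MIN:
        raise ValueError(f"r2_min must be one of {ALLOWED_R2_MIN}, got {r2_min}")
    thr = effective_threshold(r2_min)
    counters = ScanCounters()
    snps = panel.snps  # already (chrom, pos) sorted
    m = len(snps)
    # Precomputed bisection ranks make the hotspot count O(1) per pair:
    # for i < j on one chromosome, k = rank_end_le(pos_j) - rank_start_le(pos_i).
    start_rank = [track.rank_start_le(s.chrom, s.pos) for s in snps]
    end_rank = [track.rank_end_le(s.chrom, s.pos) for s in snps]

    pairs: list[LRLDPair] = []
    for i in range(m):
        si = snps[i]
        for j in range(i + 1, m):
            sj = snps[j]
            if si.chrom != sj.chrom:
                separation = DIFF_CHROM
            else:
                k = end_rank[j] - start_rank[i]
                if k <= 0:
                    counters.same_block += 1
                    continue
                separation = f"HOTSPOTS:{k}"
            counters.candidates += 1
            try:
                stats = ld_core.compute_ld(
                    panel.column(i), panel.column(j), min_haplotypes=min_haplotypes
                )
            except ld_core.MonomorphicError:
                counters.monomorphic += 1
                continue
            except ld_core.InsufficientDataError:
                counters.low_n += 1
                continue
            if stats.r2 >= thr:
                pairs.append(LRLDPair(si, sj, panel.population_label,
                                      stats, separation))
                counters.emitted += 1
            else:
                counters.below_threshold += 1
    pairs.sort(key=lambda p: (p.snp1, p.snp2))
    return pairs, counters
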