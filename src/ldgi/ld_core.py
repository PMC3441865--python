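"""Linkage-disequilibrium statistics on phased haplotype columns.

All quantities are defined on haplotypes, never genotypes: each diploid
individual contributes two rows to a panel, and a "column" is the allele
vector of one SNP across those haplotypes (0 = reference-coded allele,
1 = alternate, :data:`MISSING` = unobserved).

For a pair of biallelic loci, let ``P_A`` and ``P_B`` be the major-allele
frequencies, ``P_a``/``P_b`` the minor frequencies, and ``P_AB`` the
frequency of haplotypes carrying the major allele at both loci.  Then

    D  = P_AB - P_A * P_B
    r2 = D**2 / (P_A * P_a * P_B * P_b)
    D' = D / min(P_A*P_B, P_a*P_b)   if D < 0
       = D / min(P_A*P_b, P_a*P_B)   if D > 0
       = 0                            if D == 0

Internally every statistic is evaluated from the integer 2x2 haplotype
contingency table with a single final division, which is algebraically
identical to the frequency formulation but avoids compounding rounding:
with ``n`` used haplotypes and major-allele counts ``nA``, ``nB`` and
joint count ``nAB``,

    n**2 * D = n*nAB - nA*nB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel for an unobserved allele in a haplotype matrix.
MISSING = -1


class LDError(Exception):
    """Base class for LD-computation failures."""


class AllMissingError(LDError):
    """Every entry of a column is missing."""


class MonomorphicError(LDError):
    """A locus carries only one allele (in the pairwise-complete subset)."""


class InsufficientDataError(LDError):
    """Fewer jointly observed haplotypes than the configured minimum."""


@dataclass(frozen=True)
class AlleleFreqs:
    """Major/minor allele frequencies at one locus.

    ``major_allele`` is the coded allele (0 or 1) designated "A"; ties at
    frequency 0.5 resolve to the reference-coded allele 0, which leaves r2
    unaffected and only fixes the sign convention of D.
    """

    p_major: float
    p_minor: float
    major_allele: int
    n_used: int


@dataclass(frozen=True)
class LDStatistics:
    """Pairwise LD summary for two loci (all frequencies on haplotypes)."""

    p_major1: float
    p_major2: float
    p_minor1: float
    p_minor2: float
    p_ab: float
    d: float
    d_prime: float
    r2: float
    n_used: int
    major_allele1: int
    major_allele2: int


def _observed(column) -> np.ndarray:
    col = np.asarray(column)
    return col[col != MISSING]


def allele_frequencies(column) -> AlleleFreqs:
    """Count alleles in one column, ignoring :data:`MISSING` entries.

    Raises
    ------
    AllMissingError
        if no allele is observed.
    MonomorphicError
        if only one allele is observed (downstream skips such pairs).
    """
    obs = _observed(column)
    n = int(obs.size)
    if n == 0:
        raise AllMissingError("column has no observed alleles")
    n1 = int(np.count_nonzero(obs))
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise MonomorphicError("column is monomorphic")
    major = 0 if n0 >= n1 else 1  # tie -> reference-coded allele
    n_major = n0 if major == 0 else n1
    return AlleleFreqs(
        p_major=n_major / n,
        p_minor=(n - n_major) / n,
        major_allele=major,
        n_used=n,
    )


def haplotype_freq_AB(col1, col2, min_haplotypes: int = 2):
    """Joint major-major haplotype frequency under pairwise-complete deletion.

    Returns ``(p_ab, n_used)`` where ``n_used`` counts haplotypes observed
    at both loci.  Major alleles are determined on the pairwise-complete
    subset so that the frequencies entering Eq.-style formulas are
    internally consistent.
    """
    a, b, n = _complete_pair(col1, col2, min_haplotypes)
    fa = allele_frequencies(a)
    fb = allele_frequencies(b)
    n_ab = int(np.count_nonzero((a == fa.major_allele) & (b == fb.major_allele)))
    return n_ab / n, n


def _complete_pair(col1, col2, min_haplotypes: int):
    c1 = np.asarray(col1)
    c2 = np.asarray(col2)
    if c1.shape != c2.shape:
        raise ValueError("columns differ in length")
    mask = (c1 != MISSING) & (c2 != MISSING)
    a = c1[mask]
    b = c2[mask]
    n = int(a.size)
    if n < min_haplotypes:
        raise InsufficientDataError(
            f"{n} jointly observed haplotypes < minimum {min_haplotypes}"
        )
    return a, b, n


def compute_ld(col1, col2, min_haplotypes: int = 40) -> LDStatistics:
    """Compute D, D' and r2 for two phased allele columns.

    Haplotypes missing at either locus are removed (pairwise-complete
    deletion); the default ``min_haplotypes`` of 40 mirrors the
    20-individual population floor.  Raises :class:`MonomorphicError` if
    either locus is monomorphic in the retained subset.
    """
    a, b, n = _complete_pair(col1, col2, min_haplotypes)
    fa = allele_frequencies(a)
    fb = allele_frequencies(b)
    n_a = round(fa.p_major * n)  # integer major counts
    n_b = round(fb.p_major * n)
    n_ab = int(np.count_nonzero((a == fa.major_allele) & (b == fb.major_allele)))

    num = n * n_ab - n_a * n_b  # n^2 * D
    d = num / (n * n)
    r2 = (num * num) / (n_a * (n - n_a) * n_b * (n - n_b))
    if num > 0:
        d_prime = num / min(n_a * (n - n_b), (n - n_a) * n_b)
    elif num < 0:
        d_prime = num / min(n_a * n_b, (n - n_a) * (n - n_b))
    else:
        d_prime = 0.0
    return LDStatistics(
        p_major1=fa.p_major,
        p_major2=fb.p_major,
        p_minor1=fa.p_minor,
        p_minor2=fb.p_minor,
        p_ab=n_ab / n,
        d=d,
        d_prime=d_prime,
        r2=r2,
        n_used=n,
        major_allele1=fa.major_allele,
        major_allele2=fb.major_allele,
    )
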