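"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately take the most literal route available —
explicit 2x2 contingency tables in floating point, linear scans over
hotspot intervals, a hard-coded standard genetic code — so they share no
code path with the package implementation they check.
"""

import itertools

import numpy as np
import pytest

from ldgi import synthetic_fixtures as sf
from ldgi.ld_core import MISSING


# ---------------------------------------------------------------------------
# independent LD oracle: literal frequency-formula implementation
# ---------------------------------------------------------------------------


def ld_oracle(col1, col2, min_haplotypes=2):
    """Brute-force D, D', r2 from an explicit 2x2 haplotype table.

    Returns (D, D_prime, r2, n_used) or None when the pair is skipped
    (too few jointly observed haplotypes, or monomorphic locus).
    """
    obs = [(a, b) for a, b in zip(col1, col2)
           if a != MISSING and b != MISSING]
    n = len(obs)
    if n < min_haplotypes:
        return None

    def major(values):
        n0 = sum(1 for v in values if v == 0)
        n1 = len(values) - n0
        if n0 == 0 or n1 == 0:
            return None
        return 0 if n0 >= n1 else 1

    maj1 = major([a for a, _ in obs])
    maj2 = major([b for _, b in obs])
    if maj1 is None or maj2 is None:
        return None
    p_a = sum(1 for a, _ in obs if a == maj1) / n
    p_b = sum(1 for _, b in obs if b == maj2) / n
    p_ab = sum(1 for a, b in obs if a == maj1 and b == maj2) / n
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    if d < 0:
        d_prime = d / min(p_a * p_b, (1 - p_a) * (1 - p_b))
    elif d > 0:
        d_prime = d / min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_prime = 0.0
    return d, d_prime, r2, n


def scan_oracle(panel, track, r2_min, min_haplotypes=40):
    """Literal double-loop scan applying both long-range criteria."""
    thr = 1.0 - 1e-9 if r2_min >= 1.0 else r2_min
    out = []
    m = len(panel.snps)
    for i, j in itertools.combinations(range(m), 2):
        s1, s2 = panel.snps[i], panel.snps[j]
        if s1.chrom == s2.chrom:
            lo, hi = sorted((s1.pos, s2.pos))
            k = sum(
                1 for s, e in track.intervals(s1.chrom)
                if lo < s and e <= hi
            )
            if k == 0:
                continue
        res = ld_oracle(panel.column(i), panel.column(j), min_haplotypes)
        if res is None:
            continue
        _, _, r2, _ = res
        if r2 >= thr:
            out.append(tuple(sorted((s1.snp_id, s2.snp_id))))
    return sorted(out)


# ---------------------------------------------------------------------------
# independent genetic-code oracle: full enumeration of the standard table
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODON_TABLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def random_column_pair(rng, n):
    """A random polymorphic column pair, sometimes strongly correlated."""
    while True:
        maf = rng.uniform(0.1, 0.9)
        c1 = (rng.random(n) < maf).astype(np.int8)
        if rng.random() < 0.5:
            flip = rng.random(n) < rng.uniform(0.0, 0.3)
            c2 = np.where(flip, 1 - c1, c1).astype(np.int8)
        else:
            c2 = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(np.int8)
        if 0 < c1.sum() < n and 0 < c2.sum() < n:
            return c1, c2


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The standard simulated study bundle (seed 1), written to disk once."""
    out = tmp_path_factory.mktemp("bundle")
    return sf.simulate_bundle(sf.default_config(), seed=1, out_dir=str(out))


@pytest.fixture(scope="session")
def small_bundle():
    """Compact scan-level panel (<= 60 SNPs), in memory only."""
    panel, track, manifest = sf.simulate_panel(sf.small_scan_config(), seed=7)
    return panel, track, manifest
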