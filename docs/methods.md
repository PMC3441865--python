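# Methods

## Model and rationale

Linkage disequilibrium (LD) between two loci is expected whenever the
loci are physically close: hitchhiking and the local scarcity of
recombination preserve allele associations within haplotype blocks.
When two SNPs show *strong* LD despite lying on different chromosomes,
or on the same chromosome but separated by a recombination hotspot, the
physical explanation is unavailable, and the correlation is read as a
candidate functional association between the genomic elements hosting
the SNPs. The package operationalizes this in three steps: detect
long-range strong-LD SNP pairs on phased haplotypes, map each SNP to
promoter/UTR/CDS features of gene models, and aggregate pairs that
connect two distinct genes into categorized gene interactions.

The inference is correlational. A detected interaction is a hypothesis
— possible mechanisms range from protein–protein contact (for
nonsynonymous–nonsynonymous coding pairs) to regulatory or
translational coupling (promoter and UTR pairs) — and can also reflect
unmodeled population substructure. The tool therefore keeps populations
separate throughout and exposes the supporting SNP pairs for every
interaction rather than collapsing them.

## LD computation

All statistics are defined on haplotypes, never genotypes; phased input
is a hard requirement and no EM/composite estimation for unphased data
is provided. For a pair of loci the implementation forms the integer
2×2 haplotype contingency table on the pairwise-complete subset
(haplotypes missing at either locus removed) and evaluates

- D = P_AB − P_A·P_B,
- r² = D² / (P_A·P_a·P_B·P_b),
- D′ = D / min(P_A·P_B, P_a·P_b) for D < 0,
  D / min(P_A·P_b, P_a·P_B) for D > 0, and 0 at D = 0,

where "A"/"B" denote the major alleles determined on that same subset.
Each statistic is a single division of exact integer products
(n²·D = n·n_AB − n_A·n_B), so results are correctly rounded doubles;
the test suite checks agreement with a literal floating-point
implementation to 1e-12 and exactness on worked tables. Numerical
choices:

- a frequency tie at 0.5 designates the reference-coded allele as
  major (deterministic; r² is unaffected, only D's sign convention);
- D′ at D = 0 is defined as 0 (the two-branch normalization is
  undefined there; r² is 0 regardless);
- with major-allele coding, relabeling 0↔1 at a locus leaves D
  unchanged except at an exact 0.5 tie, where the tie-break follows the
  coded allele and D changes sign — r² is invariant always;
- monomorphic-in-subset loci make the statistic undefined; such pairs
  are skipped and counted, not imputed;
- "complete" LD (the r² = 1 tier) is tested with tolerance 1e-9, since
  exact floating-point equality is not meaningful.

## Long-range criterion

A pair is long range if the SNPs are on different chromosomes, or if at
least one *merged* hotspot interval [s, e) lies entirely inside the
open gap between the positions (pos_lo < s and e ≤ pos_hi). A hotspot
overlapping a SNP position does not cleanly separate the loci and is
not counted — the conservative reading of "separated by". Hotspot
intervals are merged (overlaps and abutments) at load, so the count
refers to recombination regions, not file fragments. Hotspots are
modeled as BED intervals; where only point estimates of hotspot centers
are available they should be expanded to intervals upstream of this
tool.

The scan enumerates unordered SNP pairs, applies the positional filter
first (O(1) per pair via precomputed bisection ranks over the merged
intervals), and computes LD only for candidates. Output is
deterministic and canonically ordered; per-population scans are
independent, so a pair found in two populations yields two records.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `r2_min` | 0.8 | — | strong-LD threshold; restricted to {0.8, 0.9, 1.0} |
| `min_individuals` | 20 | individuals | population floor; smaller panels are dropped |
| `min_haplotypes` | 40 | haplotypes | per-pair floor after missing-data removal (= 20 individuals) |
| promoter length | 2000 | bp | upstream window defining the promoter |

Thresholding is on r² only; D′ is reported but never filtered on.

## Feature annotation

Coordinates are 0-based half-open everywhere internally; VCF and GFF3
are converted at the I/O boundary, BED passes through. The promoter is
gene-level: the 2 kb upstream of the 5′-most transcription start across
the gene's transcripts, [tss−2000, tss) on the plus strand and
[tss+1, tss+2001) on the minus strand (the TSS base itself excluded on
both), clamped at chromosome bounds. Within one transcript an exonic
position is either CDS or UTR; across transcripts and overlapping genes
*every* placement is reported, which deliberately produces duplicate
pair records with different genomic types.

Coding effects substitute the alternate allele into the containing
codon of the spliced CDS (reverse-complemented into reading order on
the minus strand) and translate with the standard genetic code.
Stop-gain/-loss counts as nonsynonymous — the binary scheme has no
nonsense class. A reference allele disagreeing with the genome FASTA is
a hard error, never a silent flip, because a flipped allele would
corrupt the effect call. Transcripts whose CDS length is not divisible
by 3 are flagged non-codable: their intervals still place SNPs in
CDS/UTR, but the coding effect is reported as missing (this is the one
place a CDS annotation carries no effect).

## Interaction aggregation

For each emitted pair, the cross product of the two SNPs' annotations
contributes one interaction record per combination with two distinct
genes; both-SNPs-in-one-gene combinations are excluded from the
interaction table (a gene linked to itself is not an interaction) but
remain visible in the pair-level table. Records aggregate by (gene
pair, category, coding subtype, population); support counts distinct
SNP pairs. Categories render the unordered feature combination in
canonical PROMOTER < CDS < UTR order, with 5′ and 3′ UTR collapsed to
UTR; mixed-feature records with one CDS side keep that side's effect as
NONSYN-NA / SYN-NA. Evidence overlay (gene-pair lists for PPI and
co-expression, SNP→trait tables) recomputes flags from scratch, so it
is idempotent; interactions with no flags are "potentially
uncharacterized". A cross-population union is a query, not a stored
merge.

## Synthetic data

The generator's role is to make every stage testable without external
downloads. It emulates the *statistical* structure of a phased
multi-chromosome panel — planted SNP pairs with analytically controlled
r², independent background SNPs, hotspot intervals, strand-aware
multi-exon gene models whose codons realize prescribed
synonymous/nonsynonymous effects, plus overlapping-gene and shared-gene
cases — and writes the exact dialects the readers consume, together
with a truth manifest listing the planted pairs (target and achieved
r²) and the expected interaction table.

Planting inverts the r² formula analytically: D = √(r²·P_A·P_a·P_B·P_b)
(positive root), P_AB = P_A·P_B + D, haplotype probabilities rounded to
integer counts by largest remainder. Infeasible targets (D exceeding
min(P_A·P_b, P_a·P_B), e.g. r² = 1 with unequal frequencies) raise an
error stating the attainable maximum. The achieved r² is re-measured on
the realized counts and recorded; the rounding error is bounded by 4/n.

The default study uses one population of 50 individuals (100
haplotypes) and 150 SNPs over three chromosomes: 25 cross-chromosome
planted pairs (targets 0.9216 and 1.0, chosen so counts are exact
integers at n = 100 and achieved r² ≥ 0.9), 4 cross-hotspot pairs, 10
same-block complete-LD decoys, 6 long-range weak-LD decoys (target
0.16), and 60 background SNPs with minor-allele frequencies drawn
uniformly from 0.15–0.5. Both decoy classes are always present so the
positional filter and the threshold are each exercised. All randomness
flows from one seed through named generators; identical seeds give
byte-identical files.

What the generator does *not* emulate: coalescent genealogies,
recombination-rate variation, demography, mutation models, genotyping
error, or realistic gene architectures. Passing tests therefore
demonstrate the correctness of the algorithms under controlled LD
structure, not the biological yield of the method on real panels; in
particular the empirical-null result (no background pair reaches
r² = 0.8 at 100 haplotypes) speaks to independent loci, whereas real
panels contain substructure that can inflate long-range LD.

## Problem sizes

The shipped study sizes — 150-SNP default panels, ≤ 60-SNP panels for
brute-force parity, ten seeds per stochastic check, 1,000 random column
pairs for the LD oracle — were chosen so the full property suite
exercises every code path in seconds while keeping the brute-force
oracles (quadratic double loops, full 576-case codon enumeration)
affordable. Correctness, not genome-scale throughput, is the contract:
the scan is quadratic in SNPs per chromosome pair and is not engineered
for a full genome-wide panel.

## Known limitations

- Only biallelic SNVs are retained; multiallelic records are dropped,
  not split, and indels/CNVs are out of scope.
- Phased input is required; phase errors masquerade as LD noise.
- Population labels are an input; the package does not cluster
  individuals, and residual substructure within a labeled population
  can produce spurious long-range LD.
- Headline counts from genome-scale panels depend on the specific
  haplotype release, annotation build and clustering used upstream and
  are not reproduced by the synthetic study.
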